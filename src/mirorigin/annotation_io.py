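"""Readers/writers for every file format the pipeline touches.

All *internal* coordinates are 0-based half-open on the forward strand.
GFF3 I/O converts to/from 1-based closed coordinates here and nowhere else.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

__all__ = [
    "GenomicInterval",
    "MirnaGene",
    "RepeatFeature",
    "GeneModel",
    "Pseudogene",
    "TruthRecord",
    "revcomp",
    "overlap_bp",
    "union_coverage_bp",
    "read_genome",
    "write_genome",
    "read_mirna_gff3",
    "write_mirna_gff3",
    "read_gene_gff3",
    "write_gene_gff3",
    "read_fasta_dict",
    "write_fasta_dict",
    "read_repeat_table",
    "write_repeat_table",
    "read_pseudogene_table",
    "write_pseudogene_table",
    "read_bed",
    "write_bed",
    "read_truth_table",
    "write_truth_table",
    "is_mite_class",
]

_COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA/RNA string (U treated as T; N kept)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on a named sequence."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def sequence(self, genome: Mapping[str, str]) -> str:
        """Strand-aware sequence slice from a genome mapping."""
        if self.chrom not in genome:
            raise KeyError(f"unknown chrom {self.chrom!r}")
        s = genome[self.chrom][self.start : self.end]
        return revcomp(s) if self.strand == "-" else s


def overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    """Strand-agnostic overlap in bp; 0 for different chromosomes."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def union_coverage_bp(target: GenomicInterval, others: Iterable[GenomicInterval]) -> int:
    """bp of `target` covered by the union of `others` (same chrom only)."""
    segs = sorted(
        (max(target.start, o.start), min(target.end, o.end))
        for o in others
        if o.chrom == target.chrom and o.start < target.end and o.end > target.start
    )
    covered = 0
    cur_s = cur_e = None
    for s, e in segs:
        if cur_e is None:
            cur_s, cur_e = s, e
        elif s <= cur_e:
            cur_e = max(cur_e, e)
        else:
            covered += cur_e - cur_s
            cur_s, cur_e = s, e
    if cur_e is not None:
        covered += cur_e - cur_s
    return covered


@dataclass
class MirnaGene:
    id: str
    precursor: GenomicInterval
    precursor_seq: str
    mature_offset: int
    mature_len: int
    family: str

    def __post_init__(self) -> None:
        if self.mature_offset < 0 or self.mature_offset + self.mature_len > len(
            self.precursor_seq
        ):
            raise ValueError(f"mature outside precursor for {self.id}")

    @property
    def mature_seq(self) -> str:
        return self.precursor_seq[self.mature_offset : self.mature_offset + self.mature_len]

    @property
    def mature_interval(self) -> GenomicInterval:
        """Genomic interval of the mature (strand-aware offset)."""
        p = self.precursor
        if p.strand == "+":
            s = p.start + self.mature_offset
        else:
            s = p.end - self.mature_offset - self.mature_len
        return GenomicInterval(p.chrom, s, s + self.mature_len, p.strand)


@dataclass
class RepeatFeature:
    interval: GenomicInterval
    family: str
    repeat_class: str
    divergence: float
    score: int = 0

    def __post_init__(self) -> None:
        if self.divergence < 0:
            raise ValueError("divergence must be >= 0")

    @property
    def is_mite(self) -> bool:
        return is_mite_class(self.repeat_class)


def is_mite_class(repeat_class: str) -> bool:
    """MITE call from a RepeatMasker-style class/family string."""
    up = repeat_class.upper()
    return "STOWAWAY" in up or "TOURIST" in up or "MITE" in up


@dataclass
class GeneModel:
    id: str
    interval: GenomicInterval
    cdna_seq: str
    protein_seq: str
    isoform_count: int = 1

    def __post_init__(self) -> None:
        if self.isoform_count < 1:
            raise ValueError("isoform_count must be >= 1")


@dataclass
class Pseudogene:
    id: str
    interval: GenomicInterval
    parent_gene: str  # gene id or "unknown"


@dataclass
class TruthRecord:
    mirna_id: str
    true_origin: str  # one of TR PR ID TD SD OT
    true_mechanism: str  # one of A B C D none
    planted_target_gene: str = "none"


# ---------------------------------------------------------------------------
# FASTA

def read_genome(path: str | Path) -> dict[str, str]:
    return read_fasta_dict(path)


def read_fasta_dict(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta_dict(seqs: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


write_genome = write_fasta_dict


# ---------------------------------------------------------------------------
# GFF3  (1-based closed on disk)

_GFF_HEADER = "##gff-version 3\n"


def write_mirna_gff3(mirnas: Iterable[MirnaGene], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(_GFF_HEADER)
        for m in mirnas:
            p = m.precursor
            fh.write(
                "\t".join(
                    [
                        p.chrom,
                        "mirorigin",
                        "miRNA_primary_transcript",
                        str(p.start + 1),
                        str(p.end),
                        ".",
                        p.strand,
                        ".",
                        f"ID={m.id};family={m.family}",
                    ]
                )
                + "\n"
            )
            mi = m.mature_interval
            fh.write(
                "\t".join(
                    [
                        mi.chrom,
                        "mirorigin",
                        "miRNA",
                        str(mi.start + 1),
                        str(mi.end),
                        ".",
                        mi.strand,
                        ".",
                        f"ID={m.id}_mature;Parent={m.id}",
                    ]
                )
                + "\n"
            )


def _parse_attrs(col9: str) -> dict[str, str]:
    out = {}
    for kv in col9.strip().split(";"):
        if kv and "=" in kv:
            k, v = kv.split("=", 1)
            out[k] = v
    return out


def read_mirna_gff3(path: str | Path, genome: Mapping[str, str]) -> list[MirnaGene]:
    """Parse miRNA_primary_transcript + child miRNA features.

    Precursor sequences are extracted from `genome` (reverse-complemented on -).
    """
    precursors: dict[str, tuple[GenomicInterval, str]] = {}
    matures: dict[str, GenomicInterval] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}:{lineno}: malformed GFF3 record")
            chrom, _, ftype, start, end, _, strand, _, attrs = parts
            if chrom not in genome:
                raise ValueError(f"{path}:{lineno}: unknown chrom {chrom!r}")
            iv = GenomicInterval(chrom, int(start) - 1, int(end), strand)
            a = _parse_attrs(attrs)
            if ftype == "miRNA_primary_transcript":
                precursors[a["ID"]] = (iv, a.get("family", a["ID"]))
            elif ftype == "miRNA":
                matures[a["Parent"]] = iv
    out = []
    for mid, (iv, family) in precursors.items():
        if mid not in matures:
            raise ValueError(f"precursor {mid} has no mature miRNA child")
        mat = matures[mid]
        if iv.strand == "+":
            offset = mat.start - iv.start
        else:
            offset = iv.end - mat.end
        out.append(
            MirnaGene(
                id=mid,
                precursor=iv,
                precursor_seq=iv.sequence(genome),
                mature_offset=offset,
                mature_len=mat.length,
                family=family,
            )
        )
    return out


def write_gene_gff3(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(_GFF_HEADER)
        for g in genes:
            iv = g.interval
            fh.write(
                "\t".join(
                    [
                        iv.chrom,
                        "mirorigin",
                        "gene",
                        str(iv.start + 1),
                        str(iv.end),
                        ".",
                        iv.strand,
                        ".",
                        f"ID={g.id};isoforms={g.isoform_count}",
                    ]
                )
                + "\n"
            )


def read_gene_gff3(
    path: str | Path, cdna: Mapping[str, str], protein: Mapping[str, str]
) -> list[GeneModel]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}:{lineno}: malformed GFF3 record")
            chrom, _, ftype, start, end, _, strand, _, attrs = parts
            if ftype != "gene":
                continue
            a = _parse_attrs(attrs)
            gid = a["ID"]
            out.append(
                GeneModel(
                    id=gid,
                    interval=GenomicInterval(chrom, int(start) - 1, int(end), strand),
                    cdna_seq=cdna.get(gid, ""),
                    protein_seq=protein.get(gid, ""),
                    isoform_count=int(a.get("isoforms", 1)),
                )
            )
    return out


# ---------------------------------------------------------------------------
# Tables (TSV; coordinates 1-based closed like RepeatMasker .out)

_REPEAT_COLS = [
    "score",
    "divergence",
    "chrom",
    "begin",
    "end",
    "strand",
    "repeat_name",
    "repeat_class_family",
]


def write_repeat_table(repeats: Iterable[RepeatFeature], path: str | Path) -> None:
    rows = [
        {
            "score": r.score,
            "divergence": f"{r.divergence:.2f}",
            "chrom": r.interval.chrom,
            "begin": r.interval.start + 1,
            "end": r.interval.end,
            "strand": r.interval.strand,
            "repeat_name": r.family,
            "repeat_class_family": r.repeat_class,
        }
        for r in repeats
    ]
    pd.DataFrame(rows, columns=_REPEAT_COLS).to_csv(path, sep="\t", index=False)


def read_repeat_table(path: str | Path) -> list[RepeatFeature]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    out = []
    for i, row in df.iterrows():
        try:
            out.append(
                RepeatFeature(
                    interval=GenomicInterval(
                        str(row["chrom"]),
                        int(row["begin"]) - 1,
                        int(row["end"]),
                        str(row["strand"]),
                    ),
                    family=str(row["repeat_name"]),
                    repeat_class=str(row["repeat_class_family"]),
                    divergence=float(row["divergence"]),
                    score=int(row["score"]),
                )
            )
        except (ValueError, KeyError) as exc:  # pragma: no cover - error path
            raise ValueError(f"{path}: line {i + 2}: {exc}") from exc
    return out


def write_pseudogene_table(pseudos: Iterable[Pseudogene], path: str | Path) -> None:
    rows = [
        {
            "id": p.id,
            "chrom": p.interval.chrom,
            "start": p.interval.start + 1,
            "end": p.interval.end,
            "strand": p.interval.strand,
            "parent_gene": p.parent_gene,
        }
        for p in pseudos
    ]
    pd.DataFrame(rows, columns=["id", "chrom", "start", "end", "strand", "parent_gene"]).to_csv(
        path, sep="\t", index=False
    )


def read_pseudogene_table(path: str | Path) -> list[Pseudogene]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [
        Pseudogene(
            id=str(r["id"]),
            interval=GenomicInterval(
                str(r["chrom"]), int(r["start"]) - 1, int(r["end"]), str(r["strand"])
            ),
            parent_gene=str(r["parent_gene"]),
        )
        for _, r in df.iterrows()
    ]


# ---------------------------------------------------------------------------
# BED6 (0-based half-open on disk, matching the format spec)

def write_bed(intervals: Iterable[tuple[GenomicInterval, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv, name in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def read_bed(path: str | Path) -> list[tuple[GenomicInterval, str]]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: malformed BED record")
            chrom, s, e = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else f"feat{lineno}"
            strand = parts[5] if len(parts) > 5 else "+"
            out.append((GenomicInterval(chrom, s, e, strand), name))
    return out


# ---------------------------------------------------------------------------
# Truth table

def write_truth_table(records: Iterable[TruthRecord], path: str | Path) -> None:
    rows = [
        {
            "mirna_id": t.mirna_id,
            "true_origin": t.true_origin,
            "true_mechanism": t.true_mechanism,
            "planted_target_gene": t.planted_target_gene,
        }
        for t in records
    ]
    pd.DataFrame(
        rows, columns=["mirna_id", "true_origin", "true_mechanism", "planted_target_gene"]
    ).to_csv(path, sep="\t", index=False)


def read_truth_table(path: str | Path) -> list[TruthRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty:
        return []
    return [
        TruthRecord(
            mirna_id=r["mirna_id"],
            true_origin=r["true_origin"],
            true_mechanism=r["true_mechanism"],
            planted_target_gene=r["planted_target_gene"],
        )
        for _, r in df.iterrows()
    ]
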