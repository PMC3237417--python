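"""Synthetic genome generator with planted miRNA origin mechanisms.

Emits a single-chromosome genome plus every annotation file the pipeline
consumes, together with a truth table, so that downstream stages are
testable without external data.  Planted loci cover the four de novo
generation mechanisms (A: inverted non-MITE copies; B: MITE shared between
a foldback locus and a target transcript; C: adjacent inverted pseudogenes
of one parent; D: pseudogenes of two paralogous parents), tandem miRNA
pairs, miRNA pairs inside collinear segmental blocks, and background loci.

Every planted hairpin is validated against the duplex criteria at emission
time (bounded retries, fresh mutations per attempt); mechanism-A loci
additionally enforce >80% similarity between the two planted copies.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import features as _features
from .annotation_io import (
    GeneModel,
    GenomicInterval,
    MirnaGene,
    Pseudogene,
    RepeatFeature,
    TruthRecord,
    read_bed,
    read_gene_gff3,
    read_genome,
    read_fasta_dict,
    read_mirna_gff3,
    read_pseudogene_table,
    read_repeat_table,
    read_truth_table,
    revcomp,
    write_bed,
    write_fasta_dict,
    write_gene_gff3,
    write_genome,
    write_mirna_gff3,
    write_pseudogene_table,
    write_repeat_table,
    write_truth_table,
)
from .hairpin import fold, mircheck

__all__ = [
    "SynthConfig",
    "Bundle",
    "HairpinPlantError",
    "plant_inverted_repeat_pair",
    "mutate_copy",
    "generate_genome",
]

_NT = np.frombuffer(b"ACGT", dtype=np.uint8)
_AA = "ACDEFGHIKLMNPQRSTVWY"

MATURE_LEN = 21


class HairpinPlantError(RuntimeError):
    """Raised when retries cannot produce a valid planted hairpin."""


@dataclass
class SynthConfig:
    genome_length: int = 150_000
    n_nonmite_id: int = 10  # mechanism A plants
    n_mite_id: int = 10  # mechanism B plants
    n_pseudo_same_parent: int = 10  # mechanism C plants
    n_pseudo_paralog: int = 10  # mechanism D plants
    n_tandem_pairs: int = 10
    n_segmental_pairs: int = 10
    n_background_mirna: int = 10
    n_coding_genes: int = 10  # filler genes on top of targets/parents/anchors
    te_fraction: float = 0.15
    mite_fraction: float = 0.5
    mutation_rate_per_site: float = 0.02
    seed: int = 0
    verify_hairpins: bool = True
    max_retries: int = 80
    chrom: str = "chr1"

    def validate(self) -> None:
        counts = [
            self.genome_length,
            self.n_nonmite_id,
            self.n_mite_id,
            self.n_pseudo_same_parent,
            self.n_pseudo_paralog,
            self.n_tandem_pairs,
            self.n_segmental_pairs,
            self.n_background_mirna,
            self.n_coding_genes,
        ]
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be >= 0")
        for f in (self.te_fraction, self.mite_fraction, self.mutation_rate_per_site):
            if not 0.0 <= f <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")


@dataclass
class Bundle:
    """In-memory annotation bundle; serialisable to/from a directory."""

    genome: dict[str, str]
    mirnas: list[MirnaGene]
    repeats: list[RepeatFeature]
    pseudogenes: list[Pseudogene]
    genes: list[GeneModel]
    truth: list[TruthRecord]
    tracks: dict[str, list[tuple[GenomicInterval, str]]]
    expression: pd.DataFrame

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_genome(self.genome, out / "genome.fa")
        write_mirna_gff3(self.mirnas, out / "mirna.gff3")
        write_repeat_table(self.repeats, out / "repeats.tsv")
        write_pseudogene_table(self.pseudogenes, out / "pseudogenes.tsv")
        write_gene_gff3(self.genes, out / "genes.gff3")
        write_fasta_dict({g.id: g.cdna_seq for g in self.genes}, out / "cdna.fa")
        write_fasta_dict({g.id: g.protein_seq for g in self.genes}, out / "protein.fa")
        write_truth_table(self.truth, out / "truth.tsv")
        tracks = out / "tracks"
        tracks.mkdir(exist_ok=True)
        for name, ivs in self.tracks.items():
            write_bed(ivs, tracks / f"{name}.bed")
        self.expression.to_csv(out / "expression.tsv", sep="\t")

    @classmethod
    def load(cls, indir: str | Path) -> "Bundle":
        d = Path(indir)
        genome = read_genome(d / "genome.fa")
        cdna = read_fasta_dict(d / "cdna.fa") if (d / "cdna.fa").exists() else {}
        prot = read_fasta_dict(d / "protein.fa") if (d / "protein.fa").exists() else {}
        tracks = {}
        if (d / "tracks").is_dir():
            for p in sorted((d / "tracks").glob("*.bed")):
                tracks[p.stem] = read_bed(p)
        expr_path = d / "expression.tsv"
        expression = (
            pd.read_csv(expr_path, sep="\t", index_col=0)
            if expr_path.exists()
            else pd.DataFrame()
        )
        return cls(
            genome=genome,
            mirnas=read_mirna_gff3(d / "mirna.gff3", genome),
            repeats=read_repeat_table(d / "repeats.tsv"),
            pseudogenes=read_pseudogene_table(d / "pseudogenes.tsv"),
            genes=read_gene_gff3(d / "genes.gff3", cdna, prot),
            truth=read_truth_table(d / "truth.tsv"),
            tracks=tracks,
            expression=expression,
        )


# ---------------------------------------------------------------------------
# sequence primitives

def rand_seq(rng: np.random.Generator, n: int) -> str:
    """i.i.d. uniform background sequence."""
    return rng.choice(_NT, size=n).tobytes().decode()


def rand_protein(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(_AA), size=n))


def mutate_copy(seq: str, rate: float, rng: np.random.Generator) -> tuple[str, int]:
    """Copy with a binomially sampled number of substitutions.

    Each substituted site changes to one of the three other bases uniformly;
    returns (copy, number_of_substitutions).
    """
    n = len(seq)
    k = int(rng.binomial(n, rate))
    if k == 0:
        return seq, 0
    pos = rng.choice(n, size=k, replace=False)
    arr = bytearray(seq.encode())
    for p in pos:
        choices = [b for b in b"ACGT" if b != arr[p]]
        arr[p] = choices[int(rng.integers(3))]
    return arr.decode(), k


def _mutate_protein(seq: str, rate: float, rng: np.random.Generator) -> str:
    n = len(seq)
    k = int(rng.binomial(n, rate))
    if k == 0:
        return seq
    pos = rng.choice(n, size=k, replace=False)
    arr = list(seq)
    for p in pos:
        choices = [a for a in _AA if a != arr[p]]
        arr[p] = choices[int(rng.integers(len(choices)))]
    return "".join(arr)


def plant_inverted_repeat_pair(
    source_seq: str, spacer_len: int, mutation_rate: float, rng: np.random.Generator
) -> tuple[str, float]:
    """Foldback locus: mutated copy + spacer + revcomp of a second copy.

    Returns (locus, arm_similarity) where similarity is the fraction of
    identical positions between the two independently mutated copies.
    """
    if len(source_seq) < 60:
        raise ValueError("source sequence must be >= 60 nt")
    if spacer_len < 3:
        raise ValueError("spacer must be >= 3 nt")
    copy1, _ = mutate_copy(source_seq, mutation_rate, rng)
    copy2, _ = mutate_copy(source_seq, mutation_rate, rng)
    matches = sum(a == b for a, b in zip(copy1, copy2))
    locus = copy1 + rand_seq(rng, spacer_len) + revcomp(copy2)
    return locus, matches / len(source_seq)


def _identity(a: str, b: str) -> float:
    return sum(x == y for x, y in zip(a, b)) / len(a)


# ---------------------------------------------------------------------------
# generator

class _Builder:
    def __init__(self, cfg: SynthConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.rng = rng
        self.parts: list[str] = []
        self.cursor = 0
        self.mirnas: list[MirnaGene] = []
        self.repeats: list[RepeatFeature] = []
        self.pseudogenes: list[Pseudogene] = []
        self.genes: list[GeneModel] = []
        self.truth: list[TruthRecord] = []

    def add(self, seq: str) -> int:
        start = self.cursor
        self.parts.append(seq)
        self.cursor += len(seq)
        return start

    def pad(self, lo: int, hi: int | None = None) -> None:
        n = lo if hi is None else int(self.rng.integers(lo, hi))
        if n > 0:
            self.add(rand_seq(self.rng, n))

    def iv(self, start: int, length: int, strand: str = "+") -> GenomicInterval:
        return GenomicInterval(self.cfg.chrom, start, start + length, strand)

    def add_gene(self, gid: str, cdna: str, prot: str) -> GeneModel:
        start = self.add(cdna)
        g = GeneModel(gid, self.iv(start, len(cdna)), cdna, prot)
        self.genes.append(g)
        self.pad(150, 500)
        return g

    def add_mirna(
        self,
        mid: str,
        locus_start: int,
        pre_lo: int,
        pre_hi: int,
        seq: str,
        mature_offset: int,
        family: str,
    ) -> MirnaGene:
        m = MirnaGene(
            id=mid,
            precursor=self.iv(locus_start + pre_lo, pre_hi - pre_lo),
            precursor_seq=seq[pre_lo:pre_hi],
            mature_offset=mature_offset,
            mature_len=MATURE_LEN,
            family=family,
        )
        self.mirnas.append(m)
        return m

    # -- hairpin helpers ----------------------------------------------------

    def _verify(self, precursor: str, mature_offset: int) -> bool:
        if not self.cfg.verify_hairpins:
            return True
        v = mircheck(fold(precursor), mature_offset, MATURE_LEN)
        return v.passed

    def _check_target(self, mature: str, cdna: str, span: tuple[int, int] | None) -> bool:
        """True when the mature has a predicted site on cdna (within span)."""
        hits = _features.scan_target_sites(mature, cdna)
        for s, e, score, _ in hits:
            if span is None or (span[0] <= s and e <= span[1]):
                return True
        return False

    def _retry(self, mechanism: str):
        raise HairpinPlantError(
            f"mechanism {mechanism}: no valid hairpin after "
            f"{self.cfg.max_retries} attempts (mutation rate "
            f"{self.cfg.mutation_rate_per_site})"
        )

    # -- plants -------------------------------------------------------------

    def plant_mechanism_a(self, k: int) -> None:
        cfg, rng = self.cfg, self.rng
        mu = cfg.mutation_rate_per_site
        arm = 80
        src = rand_seq(rng, int(rng.integers(800, 1400)))
        for _ in range(cfg.max_retries):
            c1, k1 = mutate_copy(src, mu, rng)
            c2, k2 = mutate_copy(src, mu, rng)
            sim = _identity(c1, c2)
            sp = int(rng.integers(4, 9))
            locus = c1 + rand_seq(rng, sp) + revcomp(c2)
            pre_lo = len(c1) - arm
            pre_hi = len(c1) + sp + arm
            pre = locus[pre_lo:pre_hi]
            mat_off = int(rng.integers(5, arm - MATURE_LEN - 5))
            if cfg.verify_hairpins and sim <= 0.8:
                continue
            if self._verify(pre, mat_off):
                break
        else:
            self._retry("A")
        start = self.add(locus)
        fam = f"nonMITE_{k}"
        self.repeats.append(
            RepeatFeature(self.iv(start, len(c1), "+"), fam, "LTR/Gypsy", 100 * k1 / len(src))
        )
        self.repeats.append(
            RepeatFeature(
                self.iv(start + len(c1) + sp, len(c2), "-"),
                fam,
                "LTR/Gypsy",
                100 * k2 / len(src),
            )
        )
        mid = f"mir-A{k}"
        self.add_mirna(mid, start, pre_lo, pre_hi, locus, mat_off, f"FAM-A{k}")
        self.pad(200, 600)
        # target transcript carrying the source region in sense orientation
        gid = f"geneTA{k}"
        cdna = rand_seq(rng, 250) + src[-(arm + 80) :] + rand_seq(rng, 250)
        self.add_gene(gid, cdna, rand_protein(rng, 200))
        self.truth.append(TruthRecord(mid, "TR", "A", gid))

    def plant_mechanism_b(self, k: int) -> None:
        cfg, rng = self.cfg, self.rng
        mu = cfg.mutation_rate_per_site
        arm, loop = 72, 8
        consensus = None
        for _ in range(cfg.max_retries):
            arm_seq = rand_seq(rng, arm)
            consensus = arm_seq + rand_seq(rng, loop) + revcomp(arm_seq)
            mite1, k1 = mutate_copy(consensus, mu, rng)
            mite2, k2 = mutate_copy(consensus, mu, rng)
            mat_off = int(rng.integers(8, arm - MATURE_LEN - 5))
            mature = mite1[mat_off : mat_off + MATURE_LEN]
            insert_at = 300
            cdna = rand_seq(rng, insert_at) + mite2 + rand_seq(rng, 300)
            ok = self._verify(mite1, mat_off)
            if ok and cfg.verify_hairpins:
                ok = self._check_target(
                    mature, cdna, (insert_at, insert_at + len(mite2))
                )
            if ok:
                break
        else:
            self._retry("B")
        start = self.add(mite1)
        fam = f"Stowaway_{k}"
        self.repeats.append(
            RepeatFeature(
                self.iv(start, len(mite1), "+"), fam, "DNA/Stowaway", 100 * k1 / len(consensus)
            )
        )
        mid = f"mir-B{k}"
        self.add_mirna(mid, start, 0, len(mite1), mite1, mat_off, f"FAM-B{k}")
        self.pad(200, 600)
        gid = f"geneTB{k}"
        gstart = self.add(cdna)
        self.genes.append(GeneModel(gid, self.iv(gstart, len(cdna)), cdna, rand_protein(rng, 200)))
        self.repeats.append(
            RepeatFeature(
                self.iv(gstart + insert_at, len(mite2), "+"),
                fam,
                "DNA/Stowaway",
                100 * k2 / len(consensus),
            )
        )
        self.pad(150, 500)
        self.truth.append(TruthRecord(mid, "TR", "B", gid))

    def _plant_pseudo_pair(
        self,
        k: int,
        mech: str,
        seg1: str,
        seg2: str,
        parent1: str,
        parent2: str,
        target_cdna: str | None,
    ) -> None:
        """Shared geometry for mechanisms C and D: p1 + spacer + rc(p2)."""
        cfg, rng = self.cfg, self.rng
        mu = cfg.mutation_rate_per_site
        arm = 80
        for _ in range(cfg.max_retries):
            p1, _ = mutate_copy(seg1, mu, rng)
            p2, _ = mutate_copy(seg2, mu, rng)
            sp = int(rng.integers(5, 9))
            locus = p1 + rand_seq(rng, sp) + revcomp(p2)
            pre_lo = len(p1) - arm
            pre_hi = len(p1) + sp + arm
            pre = locus[pre_lo:pre_hi]
            # mature on the 3' arm: antisense to the parent transcript
            mat_off = arm + sp + int(rng.integers(5, arm - MATURE_LEN - 5))
            ok = self._verify(pre, mat_off)
            if ok and cfg.verify_hairpins and target_cdna is not None:
                mature = pre[mat_off : mat_off + MATURE_LEN]
                ok = self._check_target(mature, target_cdna, None)
            if ok:
                break
        else:
            self._retry(mech)
        start = self.add(locus)
        self.pseudogenes.append(
            Pseudogene(f"pseudo{mech}{k}a", self.iv(start, len(p1), "+"), parent1)
        )
        self.pseudogenes.append(
            Pseudogene(
                f"pseudo{mech}{k}b", self.iv(start + len(p1) + sp, len(p2), "-"), parent2
            )
        )
        mid = f"mir-{mech}{k}"
        self.add_mirna(mid, start, pre_lo, pre_hi, locus, mat_off, f"FAM-{mech}{k}")
        self.pad(200, 600)
        self.truth.append(
            TruthRecord(mid, "PR", mech, parent1 if mech == "C" else "none")
        )

    def plant_mechanism_c(self, k: int) -> None:
        rng = self.rng
        cdna = rand_seq(rng, 820)
        gid = f"genePC{k}"
        seg = cdna[260:560]
        self._plant_pseudo_pair(k, "C", seg, seg, gid, gid, cdna)
        self.add_gene(gid, cdna, rand_protein(rng, 220))

    def plant_mechanism_d(self, k: int) -> None:
        rng = self.rng
        cdna1 = rand_seq(rng, 820)
        cdna2, _ = mutate_copy(cdna1, 0.04, rng)
        prot1 = rand_protein(rng, 220)
        prot2 = _mutate_protein(prot1, 0.05, rng)
        g1, g2 = f"genePD{k}a", f"genePD{k}b"
        self._plant_pseudo_pair(k, "D", cdna1[260:560], cdna2[260:560], g1, g2, None)
        self.add_gene(g1, cdna1, prot1)
        self.add_gene(g2, cdna2, prot2)

    def _plant_hairpin_locus(
        self, mid: str, family: str, src: str, truth: TruthRecord | None
    ) -> MirnaGene:
        cfg, rng = self.cfg, self.rng
        for _ in range(cfg.max_retries):
            locus, _ = plant_inverted_repeat_pair(
                src, int(rng.integers(4, 9)), cfg.mutation_rate_per_site, rng
            )
            mat_off = int(rng.integers(5, len(src) - MATURE_LEN - 5))
            if self._verify(locus, mat_off):
                break
        else:
            self._retry("background/tandem/segmental hairpin")
        start = self.add(locus)
        m = self.add_mirna(mid, start, 0, len(locus), locus, mat_off, family)
        if truth is not None:
            self.truth.append(truth)
        return m

    def plant_tandem_pair(self, k: int) -> None:
        rng = self.rng
        src = rand_seq(rng, 75)
        fam = f"FAM-TD{k}"
        self._plant_hairpin_locus(
            f"mir-TD{k}a", fam, src, TruthRecord(f"mir-TD{k}a", "TD", "none")
        )
        self.pad(800, 9000)
        self._plant_hairpin_locus(
            f"mir-TD{k}b", fam, src, TruthRecord(f"mir-TD{k}b", "TD", "none")
        )
        self.pad(300, 800)

    def plant_background_mirna(self, k: int) -> None:
        src = rand_seq(self.rng, 75)
        self._plant_hairpin_locus(
            f"mir-OT{k}", f"FAM-OT{k}", src, TruthRecord(f"mir-OT{k}", "OT", "none")
        )
        self.pad(300, 800)

    def add_background_repeat(self, k: int) -> int:
        rng, cfg = self.rng, self.cfg
        if rng.random() < cfg.mite_fraction:
            n = int(rng.integers(150, 451))
            fam, klass = f"bgMITE_{k}", "DNA/Tourist"
        else:
            n = int(rng.integers(800, 3001))
            fam, klass = f"bgTE_{k}", "LTR/Copia"
        start = self.add(rand_seq(rng, n))
        strand = "+" if rng.random() < 0.5 else "-"
        self.repeats.append(
            RepeatFeature(self.iv(start, n, strand), fam, klass, float(rng.uniform(5, 30)))
        )
        self.pad(150, 500)
        return n


def generate_genome(cfg: SynthConfig) -> Bundle:
    """Build the full synthetic bundle for a configuration (deterministic)."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    b = _Builder(cfg, rng)
    mu = cfg.mutation_rate_per_site

    b.pad(600, 1200)

    # -- segmental block 1: anchor genes with miRNAs between them
    seg_sources = [rand_seq(rng, 75) for _ in range(cfg.n_segmental_pairs)]
    anchor_cdnas: list[str] = []
    anchor_prots: list[str] = []
    n_anchors = 6 if cfg.n_segmental_pairs else 0
    for i in range(n_anchors):
        anchor_cdnas.append(rand_seq(rng, 800))
        anchor_prots.append(rand_protein(rng, 200))
    for i in range(n_anchors):
        b.add_gene(f"anchorA{i}", anchor_cdnas[i], anchor_prots[i])
        if i == 0:
            for k, src in enumerate(seg_sources):
                b._plant_hairpin_locus(
                    f"mir-SD{k}a",
                    f"FAM-SD{k}",
                    src,
                    TruthRecord(f"mir-SD{k}a", "SD", "none"),
                )
                b.pad(150, 400)
    block1_end = b.cursor

    # -- middle section: mechanism plants, tandem pairs, background
    for k in range(cfg.n_nonmite_id):
        b.plant_mechanism_a(k)
    for k in range(cfg.n_mite_id):
        b.plant_mechanism_b(k)
    for k in range(cfg.n_pseudo_same_parent):
        b.plant_mechanism_c(k)
    for k in range(cfg.n_pseudo_paralog):
        b.plant_mechanism_d(k)
    for k in range(cfg.n_tandem_pairs):
        b.plant_tandem_pair(k)
    for k in range(cfg.n_background_mirna):
        b.plant_background_mirna(k)

    n_middle_genes = len(b.genes) - n_anchors
    # keep anchor pairs outside the tandem-duplication rank window, and pad
    # filler genes so segmental anchors are >= 20 gene ranks apart
    n_filler = cfg.n_coding_genes
    if cfg.n_segmental_pairs:
        n_filler = max(n_filler, 21 - n_middle_genes)
    for i in range(n_filler):
        b.add_gene(
            f"gene{i}",
            rand_seq(rng, int(rng.integers(700, 1100))),
            rand_protein(rng, int(rng.integers(180, 260))),
        )

    # -- background repeats up to the requested genome TE fraction
    planted_repeat_bp = sum(r.interval.length for r in b.repeats)
    target_bp = int(cfg.te_fraction * cfg.genome_length)
    k = 0
    while planted_repeat_bp < target_bp and k < 10_000:
        planted_repeat_bp += b.add_background_repeat(k)
        k += 1

    # -- segmental block 2: paralogous anchors with miRNA copies inside
    if cfg.n_segmental_pairs:
        if b.cursor - block1_end < 16_000:
            b.pad(16_000 - (b.cursor - block1_end))
        for i in range(n_anchors):
            cdna2, _ = mutate_copy(anchor_cdnas[i], max(mu, 0.01), rng)
            prot2 = _mutate_protein(anchor_prots[i], 0.02, rng)
            b.add_gene(f"anchorB{i}", cdna2, prot2)
            if i == 0:
                for k, src in enumerate(seg_sources):
                    b._plant_hairpin_locus(
                        f"mir-SD{k}b",
                        f"FAM-SD{k}",
                        src,
                        TruthRecord(f"mir-SD{k}b", "SD", "none"),
                    )
                    b.pad(150, 400)

    if b.cursor < cfg.genome_length:
        b.pad(cfg.genome_length - b.cursor)

    genome = {cfg.chrom: "".join(b.parts)}
    glen = len(genome[cfg.chrom])

    # -- optional tracks
    tracks: dict[str, list[tuple[GenomicInterval, str]]] = {
        "sirna": [],
        "promoter": [],
        "methylcytosine": [],
        "polymorphic": [],
    }
    for m in b.mirnas:
        p = m.precursor
        if rng.random() < 0.4:
            for j in range(int(rng.integers(1, 4))):
                off = int(rng.integers(0, p.length - 21))
                tracks["sirna"].append(
                    (GenomicInterval(p.chrom, p.start + off, p.start + off + 21), f"si_{m.id}_{j}")
                )
        if rng.random() < 0.5 and p.start > 1000:
            for j in range(int(rng.integers(1, 3))):
                off = int(rng.integers(1, 995))
                tracks["promoter"].append(
                    (GenomicInterval(p.chrom, p.start - off - 8, p.start - off), f"tata_{m.id}_{j}")
                )
    for name, dens in (("methylcytosine", 0.002), ("polymorphic", 0.003)):
        n_sites = int(dens * glen)
        pos = np.sort(rng.choice(glen - 1, size=n_sites, replace=False))
        tracks[name] = [
            (GenomicInterval(cfg.chrom, int(x), int(x) + 1), f"{name[:4]}{i}")
            for i, x in enumerate(pos)
        ]

    expr = pd.DataFrame(
        {
            "cond1": rng.lognormal(4, 1, len(b.genes)).round(2),
            "cond2": rng.lognormal(4, 1, len(b.genes)).round(2),
            "cond3": rng.lognormal(4, 1, len(b.genes)).round(2),
        },
        index=pd.Index([g.id for g in b.genes], name="gene_id"),
    )

    return Bundle(
        genome=genome,
        mirnas=b.mirnas,
        repeats=b.repeats,
        pseudogenes=b.pseudogenes,
        genes=b.genes,
        truth=b.truth,
        tracks=tracks,
        expression=expr,
    )


def bundle_digest(outdir: str | Path) -> dict[str, str]:
    """SHA256 of every emitted file (regenerability checks)."""
    out = {}
    for p in sorted(Path(outdir).rglob("*")):
        if p.is_file():
            out[str(p.relative_to(outdir))] = hashlib.sha256(p.read_bytes()).hexdigest()
    return out
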