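"""Synthetic inputs with planted ground truth for every pipeline stage.

The generators emulate, at the level of summary tables, the data a
neoantigen vaccine study produces: tumour/normal allele counts at candidate
SNV sites, transcript models with RNA read support at mutation sites, a
deterministic pseudo affinity predictor, ELISpot plates (one row per spot),
and pre/post-vaccine TCR clonotype tables.  Each generator returns the
planted truth alongside the data so that recovery can be asserted.

Simulation is count-level only: no reads, no alignment.  One global seed
fans out to fixed per-generator child streams, so adding or re-running one
generator never perturbs another's output.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
NUCLEOTIDES = "ACGT"

# genetic code restricted to sense codons (no stop), used to build CDSs
_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}
SENSE_CODONS = sorted(c for c, aa in _CODON_TABLE.items() if aa != "*")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# fixed child-stream offsets (design: one global seed fans out)
_STREAM_PILEUP = 1
_STREAM_TRANSCRIPTOME = 2
_STREAM_ELISPOT = 4
_STREAM_TCR = 5

PILEUP_COLUMNS = ["chrom", "pos", "ref", "alt", "t_ref", "t_alt", "n_ref", "n_alt"]
ANNOTATION_COLUMNS = ["transcript_id", "gene", "chrom", "cds_start", "cds_end", "strand"]
RNA_COLUMNS = ["chrom", "pos", "ref_reads", "alt_reads"]
ELISPOT_COLUMNS = ["well_id", "condition", "replicate", "spot_intensity", "spot_size"]
CLONOTYPE_COLUMNS = ["cdr3_aa", "count"]


class ConfigError(ValueError):
    """A SimulationConfig field violates its invariant."""


class InputError(ValueError):
    """Malformed direct input (e.g. non-amino-acid peptide character)."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study-level parameters for all synthetic generators.

    Defaults describe one emulated patient: ~100x tumour/normal exome
    coverage, somatic VAFs typical of a moderately pure tumour, a per-read
    alt-allele noise rate of 0.5%, duplicate ELISpot wells with ~50 spots
    per well, and a TCR repertoire of a few thousand clonotypes.
    """

    seed: int = 0
    # tumour/normal count table
    n_sites: int = 2000
    true_somatic_fraction: float = 0.1
    tumour_depth_mean: float = 100.0
    normal_depth_mean: float = 100.0
    true_vaf_range: tuple[float, float] = (0.2, 0.5)
    noise_error_rate: float = 0.005
    # transcriptome / RNA support
    n_transcripts: int = 30
    protein_length_range: tuple[int, int] = (300, 800)
    rna_depth_mean: float = 50.0
    rna_zero_fraction: float = 0.1
    # HLA typing of the emulated patient
    n_alleles_classI: int = 6
    n_alleles_classII: int = 2
    planted_strong_binder_fraction: float = 0.05
    # ELISpot plate
    elispot_n_conditions: int = 10
    elispot_positive_fraction: float = 0.3
    elispot_base_spots: float = 50.0
    elispot_positive_multiplier: float = 3.0
    # TCR repertoire
    tcr_n_clonotypes: int = 2000
    tcr_depth: int = 20000
    tcr_expanded_fraction: float = 0.005

    def __post_init__(self) -> None:
        proportions = [
            "true_somatic_fraction", "noise_error_rate", "rna_zero_fraction",
            "planted_strong_binder_fraction", "elispot_positive_fraction",
            "tcr_expanded_fraction",
        ]
        for name in proportions:
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1], got {v!r}")
        counts = [
            "n_sites", "n_transcripts", "n_alleles_classI", "n_alleles_classII",
            "elispot_n_conditions", "tcr_n_clonotypes", "tcr_depth",
        ]
        for name in counts:
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ConfigError(f"{name} must be a non-negative integer, got {v!r}")
        positives = [
            "tumour_depth_mean", "normal_depth_mean", "rna_depth_mean",
            "elispot_base_spots", "elispot_positive_multiplier",
        ]
        for name in positives:
            v = getattr(self, name)
            if not v > 0:
                raise ConfigError(f"{name} must be positive, got {v!r}")
        lo, hi = self.true_vaf_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ConfigError(f"true_vaf_range must be ordered within [0, 1], got {self.true_vaf_range!r}")
        plo, phi = self.protein_length_range
        if not (3 <= plo <= phi):
            raise ConfigError(f"protein_length_range must be ordered with min >= 3, got {self.protein_length_range!r}")
        if not isinstance(self.seed, (int, np.integer)):
            raise ConfigError(f"seed must be an integer, got {self.seed!r}")


def _child_rng(seed: int, stream: int) -> np.random.Generator:
    # SeedSequence spawn keyed on (seed, stream): independent per generator
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(stream,)))


def translate_cds(cds: str) -> str:
    """Translate an in-frame CDS; raises on length not divisible by 3."""
    if len(cds) % 3 != 0:
        raise InputError(f"CDS length {len(cds)} not divisible by 3")
    return "".join(_CODON_TABLE[cds[i:i + 3]] for i in range(0, len(cds), 3))


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# tumour/normal allele counts
# ---------------------------------------------------------------------------

_SITE_SPACING = 10_000  # leaves room for a transcript CDS around each site


def gen_tumour_normal_counts(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate per-site tumour/normal allele counts with planted somatic truth.

    Depths are Poisson around the configured means (floored at 1 read).
    True somatic sites draw tumour alt reads Binomial(depth, VAF) with VAF
    uniform on ``true_vaf_range``; their normal alt reads, and both alleles
    at null sites, are Binomial(depth, ``noise_error_rate``).

    Returns ``(sites, truth)``; ``truth`` records chrom, pos, ref, alt and
    the planted VAF of every somatic site.
    """
    rng = _child_rng(config.seed, _STREAM_PILEUP)
    n = config.n_sites
    pos = (np.arange(n, dtype=np.int64) + 1) * _SITE_SPACING
    ref_idx = rng.integers(0, 4, size=n)
    alt_shift = rng.integers(1, 4, size=n)
    alt_idx = (ref_idx + alt_shift) % 4
    nts = np.array(list(NUCLEOTIDES))

    t_depth = np.maximum(rng.poisson(config.tumour_depth_mean, size=n), 1)
    n_depth = np.maximum(rng.poisson(config.normal_depth_mean, size=n), 1)

    n_somatic = int(round(n * config.true_somatic_fraction))
    somatic_idx = np.sort(rng.choice(n, size=n_somatic, replace=False)) if n_somatic else np.array([], dtype=int)
    is_somatic = np.zeros(n, dtype=bool)
    is_somatic[somatic_idx] = True

    lo, hi = config.true_vaf_range
    vaf = np.full(n, config.noise_error_rate)
    vaf[is_somatic] = rng.uniform(lo, hi, size=n_somatic)

    t_alt = rng.binomial(t_depth, vaf)
    n_alt = rng.binomial(n_depth, config.noise_error_rate)

    sites = pd.DataFrame({
        "chrom": "chr1",
        "pos": pos,
        "ref": nts[ref_idx],
        "alt": nts[alt_idx],
        "t_ref": t_depth - t_alt,
        "t_alt": t_alt,
        "n_ref": n_depth - n_alt,
        "n_alt": n_alt,
    })
    truth = sites.loc[is_somatic, ["chrom", "pos", "ref", "alt"]].copy()
    truth["vaf"] = vaf[is_somatic]
    return sites, truth.reset_index(drop=True)


# ---------------------------------------------------------------------------
# transcript models and RNA support
# ---------------------------------------------------------------------------

def _pick_mutated_codon(rng: np.random.Generator, wt_base: str, mut_base: str) -> tuple[str, int] | None:
    """Choose (codon, offset) so replacing offset wt_base->mut_base is missense.

    Falls back to any sense->sense substitution when no missense exists.
    """
    missense, sense = [], []
    for codon in SENSE_CODONS:
        for off in range(3):
            if codon[off] != wt_base:
                continue
            mutant = codon[:off] + mut_base + codon[off + 1:]
            if _CODON_TABLE[mutant] == "*":
                continue
            if _CODON_TABLE[mutant] != _CODON_TABLE[codon]:
                missense.append((codon, off))
            else:
                sense.append((codon, off))
    pool = missense or sense
    if not pool:
        return None
    return pool[rng.integers(0, len(pool))]


def gen_transcriptome(
    config: SimulationConfig, truth: pd.DataFrame
) -> tuple[dict[str, str], pd.DataFrame, pd.DataFrame]:
    """Build transcript models hosting every truth somatic site, plus RNA counts.

    Each truth site is assigned to an interior codon of its own transcript;
    the genomic CDS interval is placed so the site falls at the chosen codon
    offset, honouring a randomly drawn strand.  Extra unmutated decoy
    transcripts are emitted on chr2 up to ``n_transcripts``.

    RNA read totals at mutation sites follow an overdispersed
    negative-binomial model with a ``rna_zero_fraction`` spike at zero;
    alt reads are Binomial(total, planted VAF).

    Returns ``(cds_by_transcript, annotation, rna_counts)``.
    """
    rng = _child_rng(config.seed, _STREAM_TRANSCRIPTOME)
    plo, phi = config.protein_length_range
    cds: dict[str, str] = {}
    annot_rows = []
    rna_rows = []

    codon_arr = np.array(SENSE_CODONS)
    for i, row in enumerate(truth.itertuples(index=False)):
        tid, gene = f"TX{i + 1:04d}", f"GENE{i + 1:04d}"
        length = int(rng.integers(plo, phi + 1))
        codons = list(codon_arr[rng.integers(0, len(codon_arr), size=length)])
        codon_i = int(rng.integers(1, length - 1))  # interior codon
        strand = "+" if rng.random() < 0.5 else "-"
        wt_base = row.ref if strand == "+" else row.ref.translate(_COMPLEMENT)
        mut_base = row.alt if strand == "+" else row.alt.translate(_COMPLEMENT)
        picked = _pick_mutated_codon(rng, wt_base, mut_base)
        if picked is None:  # pragma: no cover - every substitution has a sense context
            continue
        codon, off = picked
        codons[codon_i] = codon
        seq = "".join(codons)
        offset_in_cds = 3 * codon_i + off
        if strand == "+":
            cds_start = int(row.pos) - offset_in_cds
        else:
            cds_end = int(row.pos) + offset_in_cds
            cds_start = cds_end - 3 * length + 1
        cds_end = cds_start + 3 * length - 1
        cds[tid] = seq
        annot_rows.append((tid, gene, row.chrom, cds_start, cds_end, strand))

        if rng.random() < config.rna_zero_fraction:
            total = 0
        else:
            # NB via gamma-Poisson, dispersion 2 -> variance mu + mu^2/2
            lam = rng.gamma(2.0, config.rna_depth_mean / 2.0)
            total = int(rng.poisson(lam))
        alt_reads = int(rng.binomial(total, row.vaf)) if total else 0
        rna_rows.append((row.chrom, int(row.pos), total - alt_reads, alt_reads))

    for j in range(len(truth), config.n_transcripts):
        tid, gene = f"TX{j + 1:04d}", f"GENE{j + 1:04d}"
        length = int(rng.integers(plo, phi + 1))
        seq = "".join(codon_arr[rng.integers(0, len(codon_arr), size=length)])
        cds_start = (j + 1) * _SITE_SPACING
        cds[tid] = seq
        annot_rows.append((tid, gene, "chr2", cds_start, cds_start + 3 * length - 1, "+"))

    annotation = pd.DataFrame(annot_rows, columns=ANNOTATION_COLUMNS)
    rna_counts = pd.DataFrame(rna_rows, columns=RNA_COLUMNS)
    return cds, annotation, rna_counts


# ---------------------------------------------------------------------------
# toy affinity predictor
# ---------------------------------------------------------------------------

def _validate_peptide(peptide: str) -> None:
    if not peptide or any(c not in AMINO_ACIDS for c in peptide):
        raise InputError(f"peptide must be a non-empty string over {AMINO_ACIDS}, got {peptide!r}")


def toy_affinity_scorer(
    peptide: str,
    allele: str,
    seed: int = 0,
    planted: dict[tuple[str, str], float] | None = None,
) -> float:
    """Deterministic pseudo-IC50 (nM) from a keyed hash of (peptide, allele, seed).

    The hash-uniform deviate is skewed toward weak binding (most random
    peptides are non-binders) and mapped onto [1, 50000] nM.  A ``planted``
    map of (peptide, allele) -> IC50 overrides the hash so selection tests
    have known answers.  Realistic HLA binding motifs are a non-goal.
    """
    _validate_peptide(peptide)
    if planted and (peptide, allele) in planted:
        return float(planted[(peptide, allele)])
    digest = hashlib.blake2b(
        f"{peptide}|{allele}|{int(seed)}".encode(), digest_size=8
    ).digest()
    u = int.from_bytes(digest, "big") / 2**64
    ic50 = 10.0 ** (math.log10(50000.0) * u**0.3)
    return float(min(max(ic50, 1.0), 50000.0))


def build_affinity_table(
    peptides: list[str],
    alleles: list[str],
    seed: int = 0,
    planted: dict[tuple[str, str], float] | None = None,
) -> pd.DataFrame:
    """Score every (peptide, allele) pair with the toy scorer."""
    rows = [
        (p, a, toy_affinity_scorer(p, a, seed=seed, planted=planted), "toy")
        for p in peptides for a in alleles
    ]
    return pd.DataFrame(rows, columns=["peptide", "allele", "ic50", "source"])


def default_hla_alleles(config: SimulationConfig) -> tuple[list[str], list[str]]:
    """A fixed emulated HLA genotype (class I A/B/C pairs, class II DRB1)."""
    class_i = ["HLA-A02:01", "HLA-A11:01", "HLA-B15:01", "HLA-B35:01",
               "HLA-C03:03", "HLA-C07:02"][: config.n_alleles_classI]
    class_ii = ["DRB1:0405", "DRB1:1201", "DRB1:1501", "DRB1:0301"][: config.n_alleles_classII]
    return class_i, class_ii


# ---------------------------------------------------------------------------
# ELISpot plate
# ---------------------------------------------------------------------------

CONTROL_CONDITION = "mDC+Ly"


def gen_elispot_plate(config: SimulationConfig) -> tuple[pd.DataFrame, list[str]]:
    """Simulate a duplicate-well ELISpot plate with planted positive peptides.

    Control wells and one condition per peptide, in duplicate.  Spot counts
    are Poisson(``elispot_base_spots``), multiplied by
    ``elispot_positive_multiplier`` for planted positives; per-spot intensity
    and size are log-normal.  Returns ``(plate, planted_positive_conditions)``
    where ``plate`` has one row per spot.
    """
    rng = _child_rng(config.seed, _STREAM_ELISPOT)
    conditions = [f"PEP{i + 1:02d}" for i in range(config.elispot_n_conditions)]
    n_pos = int(round(config.elispot_n_conditions * config.elispot_positive_fraction))
    planted = sorted(rng.choice(conditions, size=n_pos, replace=False).tolist()) if n_pos else []
    planted_set = set(planted)

    rows = []
    well_no = 0
    for condition in [CONTROL_CONDITION] + conditions:
        mult = config.elispot_positive_multiplier if condition in planted_set else 1.0
        for replicate in (1, 2):
            well_no += 1
            # 96-well coordinates, extra plates prefixed P2, P3, ...
            slot, plate_no = (well_no - 1) % 96, (well_no - 1) // 96 + 1
            well_id = f"{'ABCDEFGH'[slot // 12]}{slot % 12 + 1:02d}"
            if plate_no > 1:
                well_id = f"P{plate_no}-{well_id}"
            n_spots = rng.poisson(config.elispot_base_spots * mult)
            intensity = rng.lognormal(mean=np.log(150.0), sigma=0.5, size=n_spots)
            size = rng.lognormal(mean=np.log(8.0), sigma=0.4, size=n_spots)
            for it, sz in zip(intensity, size):
                rows.append((well_id, condition, replicate, float(it), float(sz)))
    plate = pd.DataFrame(rows, columns=ELISPOT_COLUMNS)
    return plate, planted


# ---------------------------------------------------------------------------
# TCR clonotype tables
# ---------------------------------------------------------------------------

def _random_cdr3(rng: np.random.Generator) -> str:
    middle = "".join(np.array(list(AMINO_ACIDS))[rng.integers(0, 20, size=rng.integers(5, 10))])
    return f"CASS{middle}QYF"


def gen_clonotype_tables(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, set[str]]:
    """Pre/post vaccine clonotype tables with planted clonal expansions.

    Pre-sample frequencies follow a power law (Zipf-like, exponent 0.8 --
    flat enough that the effective clonotype number is in the hundreds, as
    in peripheral blood).  The post sample copies the pre frequency vector
    and boosts a planted subset of rare clonotypes to 0.8-3% before
    renormalising, so each planted clonotype exceeds the 0.5% display
    threshold in expectation and the boost concentrates the repertoire
    (both diversity indices fall).  Counts are multinomial at
    ``tcr_depth``.  Returns ``(pre, post, truth)``.
    """
    rng = _child_rng(config.seed, _STREAM_TCR)
    n = config.tcr_n_clonotypes
    cdr3 = []
    seen = set()
    while len(cdr3) < n:
        c = _random_cdr3(rng)
        if c not in seen:
            seen.add(c)
            cdr3.append(c)
    ranks = np.arange(1, n + 1, dtype=float)
    p_pre = ranks ** -0.8
    p_pre /= p_pre.sum()

    n_exp = int(round(n * config.tcr_expanded_fraction))
    p_post = p_pre.copy()
    if n_exp:
        rare = np.where(p_pre <= 0.005)[0]
        chosen = rng.choice(rare, size=min(n_exp, len(rare)), replace=False)
        p_post[chosen] = rng.uniform(0.008, 0.03, size=len(chosen))
        p_post /= p_post.sum()
        truth = {cdr3[i] for i in chosen}
    else:
        truth = set()

    pre_counts = rng.multinomial(config.tcr_depth, p_pre)
    post_counts = rng.multinomial(config.tcr_depth, p_post)

    def _table(counts: np.ndarray) -> pd.DataFrame:
        keep = counts > 0
        return pd.DataFrame({
            "cdr3_aa": np.array(cdr3)[keep],
            "count": counts[keep].astype(int),
        })

    return _table(pre_counts), _table(post_counts), truth


# ---------------------------------------------------------------------------
# plain-text writers (fixed column schemas)
# ---------------------------------------------------------------------------

def write_pileup_tsv(sites: pd.DataFrame, path) -> None:
    sites.to_csv(path, sep="\t", index=False, columns=PILEUP_COLUMNS)


def write_annotation_tsv(annotation: pd.DataFrame, path) -> None:
    annotation.to_csv(path, sep="\t", index=False, columns=ANNOTATION_COLUMNS)


def write_rna_tsv(rna_counts: pd.DataFrame, path) -> None:
    rna_counts.to_csv(path, sep="\t", index=False, columns=RNA_COLUMNS)


def write_fasta(cds: dict[str, str], path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(seq), id=tid, description="") for tid, seq in cds.items()]
    seqio_write(records, str(path), "fasta")


def write_elispot_csv(plate: pd.DataFrame, path) -> None:
    plate.to_csv(path, index=False, columns=ELISPOT_COLUMNS)


def write_clonotype_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, columns=CLONOTYPE_COLUMNS)
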