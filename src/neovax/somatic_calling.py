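"""Somatic SNV calling from tumour/normal allele counts.

A site is called somatic when it passes all six criteria used by
Fisher's-exact-test-based exome pipelines: mean base quality >= 15 (when
supplied; count tables are assumed pre-filtered otherwise), sequencing
depth >= 10, variant-supporting depth >= 4, tumour variant allele
frequency >= 10%, normal variant allele frequency < 2%, and a Fisher's
exact test p-value < 0.05 on the 2x2 tumour/normal x alt/ref count table.

Calls are annotated against supplied single-exon transcript models by
codon substitution under the standard genetic code (a deliberately minimal
annotator: SNVs only, strand-aware, adjacent SNVs in neighbouring or shared
codons merged into multi-residue changes), and mRNA expression at each
mutation site is confirmed from an RNA read-count table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .synthetic_data import reverse_complement, translate_cds

CALL_COLUMNS = [
    "chrom", "pos", "ref", "alt", "t_ref", "t_alt", "n_ref", "n_alt",
    "tumour_vaf", "normal_vaf", "p_value",
]


class AnnotationError(ValueError):
    """A transcript model is unusable (e.g. CDS length not divisible by 3)."""


@dataclass(frozen=True)
class CallerParams:
    """Thresholds of the six-criteria somatic filter.

    ``min_tumour_vaf`` and the depth criteria are inclusive (>=);
    ``max_normal_vaf`` and ``max_p`` are exclusive (<) bounds.  The stated
    depth criterion is applied to tumour depth; the normal sample gets its
    own minimum (same default) since count tables carry both.
    """

    min_base_quality: float = 15.0
    min_depth: int = 10
    min_normal_depth: int = 10
    min_variant_depth: int = 4
    min_tumour_vaf: float = 0.10
    max_normal_vaf: float = 0.02
    max_p: float = 0.05
    alternative: str = "two-sided"

    def __post_init__(self) -> None:
        for name in ("min_base_quality", "min_depth", "min_normal_depth", "min_variant_depth"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("min_tumour_vaf", "max_normal_vaf", "max_p"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v!r}")
        if self.alternative not in ("two-sided", "less", "greater"):
            raise ValueError(f"unknown alternative {self.alternative!r}")


def fisher_exact_p(t_alt: int, t_ref: int, n_alt: int, n_ref: int,
                   alternative: str = "two-sided") -> float:
    """Fisher's exact test p-value for the 2x2 table [[t_alt, t_ref], [n_alt, n_ref]].

    Two-sided by exact-probability summation (all tables with the observed
    margins whose hypergeometric probability does not exceed the observed
    table's).  An all-zero table carries no information and returns 1.0 with
    a warning.
    """
    counts = (t_alt, t_ref, n_alt, n_ref)
    if any(c < 0 for c in counts):
        raise ValueError(f"counts must be non-negative, got {counts}")
    if sum(counts) == 0:
        warnings.warn("all-zero 2x2 table: Fisher p-value undefined, returning 1.0")
        return 1.0
    return float(fisher_exact([[t_alt, t_ref], [n_alt, n_ref]], alternative=alternative)[1])


def call_variants(sites: pd.DataFrame, params: CallerParams | None = None) -> pd.DataFrame:
    """Apply the six-criteria filter; return passing sites sorted by (chrom, pos).

    The Fisher test is evaluated only for sites surviving the cheap
    count-based criteria.  Emitted calls carry tumour/normal VAFs and the
    p-value.
    """
    params = params or CallerParams()
    if sites.empty:
        return pd.DataFrame(columns=CALL_COLUMNS)
    df = sites.copy()
    if "mean_base_quality" in df.columns:
        df = df[df["mean_base_quality"] >= params.min_base_quality]
    t_depth = df["t_ref"] + df["t_alt"]
    n_depth = df["n_ref"] + df["n_alt"]
    with np.errstate(invalid="ignore"):
        df["tumour_vaf"] = np.where(t_depth > 0, df["t_alt"] / t_depth, 0.0)
        df["normal_vaf"] = np.where(n_depth > 0, df["n_alt"] / n_depth, 0.0)
    keep = (
        (t_depth >= params.min_depth)
        & (n_depth >= params.min_normal_depth)
        & (df["t_alt"] >= params.min_variant_depth)
        & (df["tumour_vaf"] >= params.min_tumour_vaf)
        & (df["normal_vaf"] < params.max_normal_vaf)
    )
    df = df[keep]
    df["p_value"] = [
        fisher_exact_p(r.t_alt, r.t_ref, r.n_alt, r.n_ref, alternative=params.alternative)
        for r in df.itertuples(index=False)
    ] if len(df) else []
    df = df[df["p_value"] < params.max_p]
    out = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    extra = [c for c in out.columns if c not in CALL_COLUMNS]
    return out[CALL_COLUMNS + extra]


# ---------------------------------------------------------------------------
# effect annotation
# ---------------------------------------------------------------------------

def _locate(annotation: pd.DataFrame, chrom: str, pos: int) -> pd.Series | None:
    hits = annotation[
        (annotation["chrom"] == chrom)
        & (annotation["cds_start"] <= pos)
        & (annotation["cds_end"] >= pos)
    ]
    return None if hits.empty else hits.iloc[0]


def _cds_offset(tx: pd.Series, pos: int) -> int:
    if tx["strand"] == "+":
        return int(pos - tx["cds_start"])
    return int(tx["cds_end"] - pos)


def _check_cds(tid: str, seq: str) -> None:
    if len(seq) % 3 != 0:
        raise AnnotationError(f"CDS of transcript {tid} has length {len(seq)}, not divisible by 3")


def annotate_variants(
    calls: pd.DataFrame, annotation: pd.DataFrame, cds: dict[str, str]
) -> pd.DataFrame:
    """Annotate calls with amino-acid effects against transcript models.

    Substitutions are applied on the coding strand (reverse-complemented on
    minus-strand transcripts) and translated under the standard genetic
    code.  Runs of calls in the same transcript whose affected codons are
    identical or adjacent are merged into one row with a multi-residue
    ``aa_change`` such as ``"I1375R L1376R"``.  Positions outside every
    supplied CDS are annotated ``non_coding``.

    Effects: ``missense``, ``synonymous``, ``stop_gain``, ``non_coding``.
    """
    out_rows = []
    annotated = calls.copy().reset_index(drop=True)
    # group by transcript for merging; non-coding calls pass through
    located = []
    for _, call in annotated.iterrows():
        tx = _locate(annotation, call["chrom"], int(call["pos"]))
        located.append(tx)

    by_tx: dict[str, list[int]] = {}
    for i, tx in enumerate(located):
        if tx is None:
            row = annotated.iloc[i].to_dict()
            row.update(effect="non_coding", aa_change="", gene="", transcript_id="")
            out_rows.append(row)
        else:
            by_tx.setdefault(tx["transcript_id"], []).append(i)

    tx_by_id = {r["transcript_id"]: r for r in (annotation.to_dict("records"))}
    for tid, idxs in by_tx.items():
        tx = pd.Series(tx_by_id[tid])
        seq = cds[tid]
        _check_cds(tid, seq)
        idxs = sorted(idxs, key=lambda i: int(annotated.iloc[i]["pos"]))
        # cluster genomically adjacent calls (same or neighbouring codon)
        clusters: list[list[int]] = []
        for i in idxs:
            pos = int(annotated.iloc[i]["pos"])
            if clusters and pos - int(annotated.iloc[clusters[-1][-1]]["pos"]) <= 1:
                clusters[-1].append(i)
            else:
                clusters.append([i])
        for cluster in clusters:
            mutant = list(seq)
            codon_idxs = set()
            for i in cluster:
                call = annotated.iloc[i]
                off = _cds_offset(tx, int(call["pos"]))
                base = call["alt"] if tx["strand"] == "+" else reverse_complement(call["alt"])
                ref_base = call["ref"] if tx["strand"] == "+" else reverse_complement(call["ref"])
                if seq[off] != ref_base:
                    raise AnnotationError(
                        f"reference mismatch in {tid} at {call['chrom']}:{call['pos']}: "
                        f"CDS has {seq[off]}, pileup ref is {ref_base}"
                    )
                mutant[off] = base
                codon_idxs.add(off // 3)
            wt_protein = translate_cds(seq)
            mut_protein = translate_cds("".join(mutant))
            parts, effect = [], "synonymous"
            for ci in sorted(codon_idxs):
                wt_aa, mut_aa = wt_protein[ci], mut_protein[ci]
                if mut_aa == wt_aa:
                    continue
                parts.append(f"{wt_aa}{ci + 1}{mut_aa}")
                if mut_aa == "*":
                    effect = "stop_gain"
                elif effect != "stop_gain":
                    effect = "missense"
            row = annotated.iloc[cluster[0]].to_dict()
            row.update(
                effect=effect,
                aa_change=" ".join(parts),
                gene=tx["gene"],
                transcript_id=tid,
            )
            out_rows.append(row)

    result = pd.DataFrame(out_rows)
    return result.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def rna_support(
    calls: pd.DataFrame, rna_counts: pd.DataFrame, min_mut_reads: int = 1
) -> pd.DataFrame:
    """Attach RNA read support at each mutation site and an ``expressed`` flag.

    A call is expressed iff the mutant-allele RNA read count is at least
    ``min_mut_reads``; sites absent from the RNA table get zero counts.
    """
    out = calls.copy()
    if out.empty:
        out["rna_mut_reads"] = pd.Series(dtype=int)
        out["rna_total_reads"] = pd.Series(dtype=int)
        out["expressed"] = pd.Series(dtype=bool)
        return out
    idx = {(r.chrom, int(r.pos)): (int(r.alt_reads), int(r.ref_reads + r.alt_reads))
           for r in rna_counts.itertuples(index=False)}
    mut, total = [], []
    for r in out.itertuples(index=False):
        m, t = idx.get((r.chrom, int(r.pos)), (0, 0))
        mut.append(m)
        total.append(t)
    out["rna_mut_reads"] = mut
    out["rna_total_reads"] = total
    out["expressed"] = out["rna_mut_reads"] >= min_mut_reads
    return out


# ---------------------------------------------------------------------------
# output writers
# ---------------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=neovax {version}
##INFO=<ID=TVAF,Number=1,Type=Float,Description="Tumour variant allele frequency">
##INFO=<ID=NVAF,Number=1,Type=Float,Description="Normal variant allele frequency">
##INFO=<ID=FEP,Number=1,Type=Float,Description="Fisher exact test p-value">
##INFO=<ID=AACH,Number=1,Type=String,Description="Amino acid change">
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=RNAMUT,Number=1,Type=Integer,Description="RNA reads supporting the mutant allele">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_vcf(calls: pd.DataFrame, path) -> None:
    """Write calls as a minimal un-normalised VCF 4.2 (SNVs only)."""
    from . import __version__

    with open(path, "w") as fh:
        fh.write(_VCF_HEADER.format(version=__version__))
        for r in calls.itertuples(index=False):
            info = [f"TVAF={r.tumour_vaf:.4f}", f"NVAF={r.normal_vaf:.4f}",
                    f"FEP={r.p_value:.3e}"]
            aach = getattr(r, "aa_change", "")
            if aach:
                info.append(f"AACH={aach.replace(' ', '_')}")
            gene = getattr(r, "gene", "")
            if gene:
                info.append(f"GENE={gene}")
            if hasattr(r, "rna_mut_reads"):
                info.append(f"RNAMUT={int(r.rna_mut_reads)}")
            fh.write(f"{r.chrom}\t{int(r.pos)}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t{';'.join(info)}\n")


def write_calls_tsv(calls: pd.DataFrame, path) -> None:
    calls.to_csv(path, sep="\t", index=False)


def read_calls_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
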