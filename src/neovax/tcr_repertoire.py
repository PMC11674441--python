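"""TCR CDR3 clonotype frequencies, diversity indices and pre/post comparison.

Diversity of a clonotype table with frequencies p_i is summarised by the
inverse Simpson index 1 / sum(p_i^2) (an effective number of clonotypes,
in [1, n]) and the Shannon index -sum(p_i log p_i) (natural log by
default, in [0, log n]).  Clonal expansion after vaccination is read from
the set of clonotypes whose frequency rises above a display threshold
(strictly more than 0.5% by default) in the post sample while at or below
it before.  Two clonality normalisations are reported, since "clonality"
has no single convention: sum(p_i^2) (the Simpson concentration,
1/inverse-Simpson) and 1 - Shannon/log(n).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic_data import InputError

DISPLAY_THRESHOLD = 0.005


@dataclass
class ClonotypeTable:
    """CDR3 amino-acid clonotypes with read counts for one sample."""

    sample_id: str
    entries: pd.DataFrame  # columns: cdr3_aa, count

    def __post_init__(self) -> None:
        df = self.entries
        if not {"cdr3_aa", "count"}.issubset(df.columns):
            raise InputError("clonotype table needs columns cdr3_aa and count")
        if len(df) and (df["count"] < 1).any():
            raise InputError("clonotype counts must be >= 1")
        if df["cdr3_aa"].duplicated().any():
            warnings.warn("duplicate CDR3 rows: summing counts")
            self.entries = df.groupby("cdr3_aa", as_index=False, sort=True)["count"].sum()

    @classmethod
    def from_counts(cls, counts: dict[str, int], sample_id: str = "") -> "ClonotypeTable":
        df = pd.DataFrame({"cdr3_aa": list(counts), "count": list(counts.values())})
        return cls(sample_id=sample_id, entries=df)

    @classmethod
    def from_tsv(cls, path, sample_id: str = "") -> "ClonotypeTable":
        df = pd.read_csv(path, sep="\t", comment="#")
        return cls(sample_id=sample_id or str(path), entries=df[["cdr3_aa", "count"]])

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class RepertoireComparison:
    emergent: tuple[str, ...]
    contracted: tuple[str, ...]
    di_pre: float
    di_post: float
    shannon_pre: float
    shannon_post: float
    clonality_simpson_pre: float
    clonality_simpson_post: float
    clonality_shannon_pre: float
    clonality_shannon_post: float


def _require_nonempty(table: ClonotypeTable) -> None:
    if len(table) == 0:
        raise InputError(f"clonotype table {table.sample_id!r} is empty")


def frequencies(table: ClonotypeTable) -> pd.DataFrame:
    """Per-clonotype proportions p_i = count_i / total; sums to 1."""
    _require_nonempty(table)
    df = table.entries.copy()
    df["frequency"] = df["count"] / df["count"].sum()
    return df[["cdr3_aa", "frequency"]]


def inverse_simpson(table: ClonotypeTable) -> float:
    """1 / sum(p_i^2), the effective number of clonotypes."""
    _require_nonempty(table)
    p = table.entries["count"].to_numpy(dtype=float)
    p /= p.sum()
    return float(1.0 / np.sum(p**2))


def shannon(table: ClonotypeTable, base: str | float = "e") -> float:
    """-sum(p_i log p_i); 0 for a single clone, log(n) for a uniform table."""
    _require_nonempty(table)
    p = table.entries["count"].to_numpy(dtype=float)
    p /= p.sum()
    h = float(-np.sum(p * np.log(p)))
    if base in ("e", math.e):
        return h
    if base in (2, "2"):
        return h / math.log(2.0)
    raise InputError(f"unsupported log base {base!r}")


def expanded_clonotypes(
    table: ClonotypeTable, threshold: float = DISPLAY_THRESHOLD
) -> pd.DataFrame:
    """Clonotypes strictly above the display threshold, by descending frequency.

    A clonotype at exactly the threshold is excluded ("more than 0.5%").
    Ties in frequency are broken lexicographically by CDR3.
    """
    freq = frequencies(table)
    out = freq[freq["frequency"] > threshold]
    return out.sort_values(
        ["frequency", "cdr3_aa"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


def compare(
    pre: ClonotypeTable, post: ClonotypeTable, threshold: float = DISPLAY_THRESHOLD
) -> RepertoireComparison:
    """Pre/post-vaccine repertoire comparison.

    Emergent clonotypes exceed the threshold post but not pre; contracted is
    the converse.  Clonotypes absent from a sample have frequency 0.
    """
    _require_nonempty(pre)
    _require_nonempty(post)
    f_pre = dict(zip(*frequencies(pre).T.values.tolist()))
    f_post = dict(zip(*frequencies(post).T.values.tolist()))
    all_cdr3 = sorted(set(f_pre) | set(f_post))
    emergent = tuple(
        c for c in all_cdr3
        if f_post.get(c, 0.0) > threshold and f_pre.get(c, 0.0) <= threshold
    )
    contracted = tuple(
        c for c in all_cdr3
        if f_pre.get(c, 0.0) > threshold and f_post.get(c, 0.0) <= threshold
    )
    h_pre, h_post = shannon(pre), shannon(post)
    return RepertoireComparison(
        emergent=emergent,
        contracted=contracted,
        di_pre=inverse_simpson(pre),
        di_post=inverse_simpson(post),
        shannon_pre=h_pre,
        shannon_post=h_post,
        clonality_simpson_pre=1.0 / inverse_simpson(pre),
        clonality_simpson_post=1.0 / inverse_simpson(post),
        clonality_shannon_pre=1.0 - h_pre / math.log(len(pre)) if len(pre) > 1 else 1.0,
        clonality_shannon_post=1.0 - h_post / math.log(len(post)) if len(post) > 1 else 1.0,
    )


def comparison_report(cmp: RepertoireComparison) -> tuple[pd.DataFrame, str]:
    """(tabular summary, JSON summary) of a repertoire comparison."""
    rows = [
        ("inverse_simpson", cmp.di_pre, cmp.di_post),
        ("shannon", cmp.shannon_pre, cmp.shannon_post),
        ("clonality_simpson", cmp.clonality_simpson_pre, cmp.clonality_simpson_post),
        ("clonality_shannon", cmp.clonality_shannon_pre, cmp.clonality_shannon_post),
        ("n_emergent", len(cmp.emergent), len(cmp.emergent)),
        ("n_contracted", len(cmp.contracted), len(cmp.contracted)),
    ]
    df = pd.DataFrame(rows, columns=["metric", "pre", "post"])
    payload = {
        "di_pre": cmp.di_pre, "di_post": cmp.di_post,
        "shannon_pre": cmp.shannon_pre, "shannon_post": cmp.shannon_post,
        "clonality_simpson_pre": cmp.clonality_simpson_pre,
        "clonality_simpson_post": cmp.clonality_simpson_post,
        "clonality_shannon_pre": cmp.clonality_shannon_pre,
        "clonality_shannon_post": cmp.clonality_shannon_post,
        "emergent": list(cmp.emergent), "contracted": list(cmp.contracted),
    }
    return df, json.dumps(payload, indent=2, sort_keys=True)
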