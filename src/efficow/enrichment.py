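"""Hypergeometric over-representation of annotation terms among DAPs.

Given a set of differentially abundant proteins (the "hits"), a
background universe (by default all quantified proteins — the testable
universe), and term→member annotation sets (GMT), each term is scored by
the upper-tail hypergeometric probability

    p = P(X ≥ k),  X ~ Hypergeometric(N, K, n)

with N the background size, K the term's members in the background, n
the hits in the background and k the annotated hits. Over-representation
only; depletion is out of scope. P-values are Benjamini–Hochberg
adjusted across the tested terms. Terms with fewer than two background
members are skipped (reported with status ``skipped_small``) to avoid
degenerate single-member terms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AnnotationSet",
    "read_gmt",
    "write_gmt",
    "bh_adjust",
    "hypergeom_enrich",
    "category_fractions",
]


@dataclass(frozen=True)
class AnnotationSet:
    """One annotation term: id, human-readable name, member protein ids."""

    term_id: str
    term_name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"term {self.term_id} has no members")


def read_gmt(path) -> list[AnnotationSet]:
    """Read annotation sets from a GMT file (term, description, members)."""
    sets = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            sets.append(AnnotationSet(fields[0], fields[1],
                                      frozenset(f for f in fields[2:] if f)))
    return sets


def write_gmt(sets: list[AnnotationSet], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in sets:
            fh.write("\t".join([s.term_id, s.term_name, *sorted(s.members)]) + "\n")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hypergeom_enrich(daps, background, annotations: list[AnnotationSet],
                     min_term_size: int = 2) -> pd.DataFrame:
    """Score every term for over-representation of `daps` in `background`.

    Returns a frame sorted by ``p_hyper`` with columns term_id,
    term_name, N, K, n, k, p_hyper, p_adj, fold_enrichment, status.
    ``fold_enrichment = (k/n)/(K/N)``. Raises if any hit is outside the
    background or the background is empty.
    """
    daps = set(map(str, daps))
    background = set(map(str, background))
    if not background:
        raise ValueError("background is empty")
    offenders = daps - background
    if offenders:
        raise ValueError(f"DAPs outside the background: {sorted(offenders)[:10]}")
    N, n = len(background), len(daps)
    rows = []
    for term in annotations:
        members = term.members & background
        K = len(members)
        k = len(members & daps)
        status = "ok" if K >= min_term_size else "skipped_small"
        # sf(k-1) = P(X >= k), upper tail inclusive
        p_hyper = float(stats.hypergeom.sf(k - 1, N, K, n)) if status == "ok" else np.nan
        fe = (k / n) / (K / N) if (status == "ok" and n > 0 and K > 0) else np.nan
        rows.append({"term_id": term.term_id, "term_name": term.term_name,
                     "N": N, "K": K, "n": n, "k": k,
                     "p_hyper": p_hyper, "fold_enrichment": fe,
                     "status": status})
    out = pd.DataFrame(rows)
    out["p_adj"] = np.nan
    tested = out["status"] == "ok"
    if tested.any():
        out.loc[tested, "p_adj"] = bh_adjust(out.loc[tested, "p_hyper"].to_numpy())
    return out.sort_values(["p_hyper", "term_id"],
                           na_position="last").reset_index(drop=True)


def category_fractions(ids, annotations: list[AnnotationSet],
                       ) -> pd.DataFrame:
    """Per-term percentage of `ids` carrying the annotation.

    Pie/bar-style summary: for each term, 100·|ids ∩ members|/|ids|.
    Terms overlap, so percentages need not sum to 100.
    """
    ids = set(map(str, ids))
    if not ids:
        raise ValueError("ids must be nonempty")
    rows = [{"term_id": t.term_id, "term_name": t.term_name,
             "k": len(ids & t.members),
             "percent": 100.0 * len(ids & t.members) / len(ids)}
            for t in annotations]
    return pd.DataFrame(rows)
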