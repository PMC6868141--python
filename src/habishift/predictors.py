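"""Collinearity filtering and candidate predictor-set enumeration.

The filtering rule: starting from all 2^p subsets of the predictor pool,
(1) drop every subset containing a pair of predictors with |Pearson r| at or
above ``r_max`` (0.70 by default); (2) drop every subset containing a member
whose variance inflation factor, computed within that subset, is at or above
``vif_max`` (5 by default); (3) drop subsets nested inside a surviving
superset.  The survivors are the maximal admissible sets.  The lattice is
pruned rather than materialized — every admissible set is an independent set
of the pairwise-conflict graph, so enumeration starts from that graph's
maximal independent sets and only descends while a VIF violation remains —
but the reported ``total_combinations`` is the conceptual 2^p.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd


@dataclass
class CandidateSets:
    """Surviving maximal predictor subsets plus filter diagnostics."""

    names: tuple
    sets: list  # list of tuples of predictor names, sorted
    total_combinations: int  # 2 ** pool size
    excluded_pairs: pd.DataFrame  # columns: a, b, r, reason
    vif_table: pd.DataFrame  # columns: subset, member, vif (visited sets)


def pairwise_correlations(values: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix over columns; NaN marks undefined pairs.

    ``values`` has evaluation cells on rows and predictors on columns.  A
    zero-variance column yields NaN correlations with every other column
    (callers treat NaN as an excluded pair); the diagonal is always 1.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] < 3:
        raise ValueError("need a 2-D matrix with at least 3 evaluation cells")
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite predictor values")
    sd = values.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(values, rowvar=False)
    r = np.atleast_2d(r)
    bad = sd < 1e-12
    r[bad, :] = np.nan
    r[:, bad] = np.nan
    np.fill_diagonal(r, 1.0)
    return r


def vif(values: np.ndarray, subset: tuple, member) -> float:
    """Variance inflation factor of ``member`` within ``subset``.

    1 / (1 - R^2) from the OLS regression (with intercept) of the member's
    column on the other subset columns.  Perfect collinearity gives +inf.
    """
    subset = tuple(subset)
    if member not in subset:
        raise ValueError("member must belong to subset")
    if len(subset) < 2:
        raise ValueError("subset must have at least 2 members")
    cols = [c for c in subset if c != member]
    y = values[:, member]
    X = np.column_stack([np.ones(len(values))] + [values[:, c] for c in cols])
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot < 1e-12:
        return float("inf")  # zero-variance member
    r2 = 1.0 - np.sum(resid**2) / ss_tot
    if r2 >= 1.0 - 1e-12:
        return float("inf")
    return float(1.0 / (1.0 - r2))


def _max_vif_violation(values: np.ndarray, subset: tuple, vif_max: float) -> list:
    if len(subset) < 2:
        return []
    return [m for m in subset if vif(values, subset, m) >= vif_max]


def enumerate_candidate_sets(
    values: np.ndarray,
    names: tuple | list,
    r_max: float = 0.70,
    vif_max: float = 5.0,
) -> CandidateSets:
    """Enumerate the maximal predictor subsets surviving both collinearity filters."""
    names = tuple(names)
    p = len(names)
    if p == 0:
        raise ValueError("empty predictor pool")
    if p > 24:
        raise ValueError("pool larger than 24 predictors is not supported")
    if values.shape[1] != p:
        raise ValueError("value matrix column count must equal pool size")

    r = pairwise_correlations(values)
    conflict = nx.Graph()
    conflict.add_nodes_from(range(p))
    pair_rows = []
    for i, j in combinations(range(p), 2):
        rij = r[i, j]
        excluded = bool(np.isnan(rij) or abs(rij) >= r_max)
        if excluded:
            conflict.add_edge(i, j)
        pair_rows.append(
            {"a": names[i], "b": names[j], "r": rij,
             "reason": ("undefined" if np.isnan(rij) else "high_r") if excluded else ""}
        )
    excluded_pairs = pd.DataFrame(pair_rows)

    # maximal independent sets of the conflict graph = maximal cliques of its complement
    seeds = [tuple(sorted(c)) for c in nx.find_cliques(nx.complement(conflict))]

    survivors: set = set()
    seen: set = set()
    vif_rows: list = []

    def descend(subset: tuple) -> None:
        if subset in seen:
            return
        seen.add(subset)
        violations = _max_vif_violation(values, subset, vif_max)
        for m in subset if len(subset) >= 2 else ():
            vif_rows.append(
                {"subset": "+".join(names[i] for i in subset),
                 "member": names[m], "vif": vif(values, subset, m)}
            )
        if not violations:
            if subset:
                survivors.add(subset)
            return
        # a violation can involve any member: descend on every one-smaller subset
        for drop in subset:
            child = tuple(x for x in subset if x != drop)
            if child:
                descend(child)

    for s in sorted(seeds):
        descend(s)

    # prune nested survivors
    maximal = [
        s for s in survivors
        if not any(s != t and set(s) <= set(t) for t in survivors)
    ]
    maximal.sort()
    sets = [tuple(names[i] for i in s) for s in maximal]
    return CandidateSets(
        names=names,
        sets=sets,
        total_combinations=2**p,
        excluded_pairs=excluded_pairs,
        vif_table=pd.DataFrame(vif_rows).drop_duplicates() if vif_rows else
        pd.DataFrame(columns=["subset", "member", "vif"]),
    )


def brute_force_candidate_sets(
    values: np.ndarray, names: tuple | list, r_max: float = 0.70, vif_max: float = 5.0
) -> list:
    """Reference enumeration materializing all 2^p subsets (p <= 16 only)."""
    names = tuple(names)
    p = len(names)
    if p > 16:
        raise ValueError("brute force limited to 16 predictors")
    r = pairwise_correlations(values)
    admissible = []
    for mask in range(1, 2**p):
        subset = tuple(i for i in range(p) if mask >> i & 1)
        ok = True
        for i, j in combinations(subset, 2):
            if np.isnan(r[i, j]) or abs(r[i, j]) >= r_max:
                ok = False
                break
        if ok and len(subset) >= 2:
            ok = not _max_vif_violation(values, subset, vif_max)
        if ok:
            admissible.append(set(subset))
    maximal = [s for s in admissible if not any(s < t for t in admissible)]
    return sorted(tuple(names[i] for i in sorted(s)) for s in maximal)
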