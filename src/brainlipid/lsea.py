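"""Lipid set enrichment analysis (LSEA) and class over-representation.

Sets are built from the lipid annotation itself — class, total acyl chain
length, total double bonds. Enrichment uses a weighted Kolmogorov-Smirnov
running sum over the fold-change-ranked lipid list: the running sum gains
|stat|^weight (normalized) at each set member and loses 1/N at every step, so
its extremum compares the weighted hit distribution against the uniform
expectation. Significance comes from permuting set membership labels; the
module over-representation test is a one-sided Fisher exact (hypergeometric
upper tail) of hub-lipid classes against the annotated-lipid background.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .chem import LipidParseError, LipidSpecies, parse_lipid_name
from .diff import bh_fdr


@dataclass(frozen=True)
class LipidSet:
    set_id: str  # e.g. "class:LPE", "length:22", "db:12"
    members: frozenset

    @property
    def facet(self) -> str:
        return self.set_id.split(":", 1)[0]


@dataclass
class EnrichmentResult:
    set_id: str
    es: float
    nes: float
    p: float
    q: float
    leading_edge: list


DEFAULT_FACETS = ("class", "total_length", "total_db")
_FACET_PREFIX = {"class": "class", "total_length": "length", "total_db": "db"}


def build_lipid_sets(
    universe: Sequence, facets: Iterable[str] = DEFAULT_FACETS, min_set_size: int = 3
) -> list[LipidSet]:
    """Group the lipid universe into sets by annotation facet.

    ``universe`` holds species names or parsed :class:`LipidSpecies`; each
    lipid joins at most one set per facet; sets smaller than ``min_set_size``
    are dropped.
    """
    parsed: list[tuple[str, LipidSpecies]] = []
    for item in universe:
        if isinstance(item, LipidSpecies):
            parsed.append((item.name, item))
        else:
            try:
                parsed.append((item, parse_lipid_name(item)))
            except LipidParseError:
                continue
    sets: dict[str, set] = {}
    for name, sp in parsed:
        for facet in facets:
            if facet == "class":
                key = f"class:{sp.lipid_class}"
            elif facet == "total_length":
                key = f"length:{sp.total_carbons}"
            elif facet == "total_db":
                key = f"db:{sp.total_double_bonds}"
            else:
                raise ValueError(f"unknown facet {facet!r}")
            sets.setdefault(key, set()).add(name)
    return [
        LipidSet(k, frozenset(v))
        for k, v in sorted(sets.items())
        if len(v) >= min_set_size
    ]


def _es_from_positions(
    positions: np.ndarray, weights_cum: np.ndarray, n_universe: int
) -> tuple[np.ndarray, np.ndarray]:
    """Signed ES for batches of hit-position rows.

    ``positions``: (B, m) sorted 0-based ranks of the set members;
    ``weights_cum``: (B, m) row-normalized cumulative hit weights. The running
    sum over ranked items gains the member's normalized weight at each hit and
    loses 1/N at every item, so extrema occur just after (maximum candidates)
    or just before (minimum candidates) a hit. Returns (ES, argext) where
    argext is the index (within the row) of the extremal hit.
    """
    after = weights_cum - (positions + 1) / n_universe
    prev = np.concatenate(
        [np.zeros((weights_cum.shape[0], 1)), weights_cum[:, :-1]], axis=1
    )
    before = prev - positions / n_universe
    top = after.max(axis=1)
    arg_top = after.argmax(axis=1)
    bottom = before.min(axis=1)
    arg_bottom = before.argmin(axis=1)
    use_top = top >= -bottom
    es = np.where(use_top, top, bottom)
    argext = np.where(use_top, arg_top, arg_bottom)
    return es, argext


def enrichment_score(
    ranked_features: Sequence[str],
    stats_by_feature: Sequence[float],
    lipid_set: LipidSet,
    weight_exponent: float = 1.0,
) -> tuple[float, list]:
    """Weighted KS enrichment score of a set in a ranked lipid list.

    ``ranked_features`` must be ordered by decreasing ranking statistic.
    Returns the signed ES and the leading edge (members at or before the
    positive extremum, or at and after the negative extremum).
    """
    ranked = list(ranked_features)
    n = len(ranked)
    if len(set(ranked)) != n:
        raise ValueError("ranked features must be unique")
    members = lipid_set.members & set(ranked)
    if not members:
        raise ValueError(f"set {lipid_set.set_id} disjoint from the ranked universe")
    if len(members) == n:
        raise ValueError("set equals the whole universe; enrichment is degenerate")
    stat = np.asarray(stats_by_feature, dtype=float)
    if not np.all(np.isfinite(stat)):
        raise ValueError("ranking statistics must be finite")
    idx = {f: i for i, f in enumerate(ranked)}
    positions = np.sort(np.array([idx[m] for m in members]))
    w = np.abs(stat[positions]) ** weight_exponent
    total = w.sum()
    wcum = (np.cumsum(w) / total if total > 0 else (np.arange(len(w)) + 1) / len(w))
    es, argext = _es_from_positions(positions[None, :], wcum[None, :], n)
    es, argext = float(es[0]), int(argext[0])
    if es >= 0:
        lead_pos = positions[: argext + 1]
    else:
        lead_pos = positions[argext:]
    leading = [ranked[i] for i in lead_pos]
    return es, leading


def lsea_test(
    log_table: pd.DataFrame,
    groups: pd.Series,
    contrast: tuple[str, str],
    sets: Sequence[LipidSet],
    n_permutations: int = 10_000,
    weight_exponent: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation LSEA of ``contrast = (group_a, group_b)`` on log2 abundances.

    Lipids are ranked by log2 fold change (A minus B); the null redraws each
    set's membership uniformly from the universe ``n_permutations`` times.
    p = (1 + #{|ES_null| >= |ES|}) / (B + 1); NES = ES / mean |ES_null|;
    BH correction within each annotation facet.
    """
    if n_permutations < 100:
        raise ValueError("need at least 100 permutations")
    rng = np.random.default_rng(seed)
    groups = groups.loc[log_table.index]
    a, b = contrast
    fc = (
        log_table.loc[(groups == a).to_numpy()].mean(axis=0)
        - log_table.loc[(groups == b).to_numpy()].mean(axis=0)
    )
    order = np.argsort(-fc.to_numpy(), kind="stable")
    ranked = [log_table.columns[i] for i in order]
    stat_ranked = fc.to_numpy()[order]
    n = len(ranked)
    abs_w = np.abs(stat_ranked) ** weight_exponent

    rows = []
    for s in sets:
        es, leading = enrichment_score(ranked, stat_ranked, s, weight_exponent)
        m = len(s.members & set(ranked))
        # null: random membership of the same size
        perm_pos = np.sort(
            np.array([rng.choice(n, size=m, replace=False) for _ in range(n_permutations)]),
            axis=1,
        )
        w = abs_w[perm_pos]
        tot = w.sum(axis=1, keepdims=True)
        tot[tot == 0] = 1.0
        wcum = np.cumsum(w, axis=1) / tot
        es_null, _ = _es_from_positions(perm_pos, wcum, n)
        p = (1 + np.sum(np.abs(es_null) >= abs(es))) / (n_permutations + 1)
        mean_null = np.abs(es_null).mean()
        nes = es / mean_null if mean_null > 0 else np.nan
        rows.append(
            {
                "set_id": s.set_id,
                "facet": s.facet,
                "size": m,
                "ES": es,
                "NES": nes,
                "p": p,
                "leading_edge": ";".join(leading),
            }
        )
    out = pd.DataFrame(rows).set_index("set_id")
    out["q"] = np.nan
    for facet, sub in out.groupby("facet"):
        out.loc[sub.index, "q"] = bh_fdr(sub["p"].to_numpy())
    return out.sort_values("p")


def class_ora(
    hub_lipids: Iterable[str],
    universe: Iterable[str],
    module: str = "",
) -> pd.DataFrame:
    """One-sided Fisher exact over-representation of lipid classes among module hubs.

    Query = hub lipids of one module; background = all annotated lipids.
    p is the hypergeometric upper tail; BH correction within the module.
    Classes absent from the universe are skipped.
    """
    hubs = set(hub_lipids)
    uni = list(dict.fromkeys(universe))
    if not hubs <= set(uni):
        raise ValueError("hub lipids must be a subset of the universe")
    if not hubs:
        return pd.DataFrame(
            columns=["module", "lipid_class", "k", "n", "K", "N", "odds_ratio", "p", "q"]
        )
    cls_of = {}
    for name in uni:
        try:
            cls_of[name] = parse_lipid_name(name).lipid_class
        except LipidParseError:
            continue
    N = len(cls_of)
    n = len([h for h in hubs if h in cls_of])
    rows = []
    for cls in sorted(set(cls_of.values())):
        K = sum(1 for c in cls_of.values() if c == cls)
        k = sum(1 for h in hubs if cls_of.get(h) == cls)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        a, bb, c, d = k, n - k, K - k, N - K - (n - k)
        odds = (a * d) / (bb * c) if bb * c > 0 else np.inf
        rows.append(
            {
                "module": module,
                "lipid_class": cls,
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "odds_ratio": odds,
                "p": p,
            }
        )
    out = pd.DataFrame(rows)
    out["q"] = bh_fdr(out["p"].to_numpy())
    out["significant_5pct_fdr"] = out["q"] < 0.05
    return out.sort_values("p").reset_index(drop=True)
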