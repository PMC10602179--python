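"""Multi-SNP haplotype risk at lead variants.

Enumerates the distinct allele strings spanned by a set of lead sites
in phased case and control haplotypes, computes each haplotype's odds
ratio against all other haplotypes pooled (Woolf confidence interval,
Haldane-Anscombe correction on zero cells), and derives the minimum
spanning network topology on Hamming distances that underlies
haplotype-network figures.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DataError, ParameterError, UndefinedStatisticError

__all__ = [
    "enumerate_haplotypes",
    "haplotype_or",
    "haplotype_table",
    "hamming_network",
]


def _hap_strings(haps: np.ndarray, sites: Sequence[int]) -> list[str]:
    h = np.asarray(haps)
    if h.ndim != 2:
        raise DataError("phased input must be a 2-D haplotype x site matrix")
    sub = h[:, list(sites)]
    if not np.isin(sub, (0, 1)).all():
        raise DataError("haplotypes must be phased 0/1 calls")
    return ["".join(map(str, row)) for row in sub]


def enumerate_haplotypes(case_haps, ctrl_haps, sites: Sequence[int]) -> pd.DataFrame:
    """Distinct lead-site haplotypes with case/control counts.

    Rows are ordered by descending total count, then lexicographically
    by haplotype string, so the output is deterministic.  Counts sum to
    the number of input haplotypes (2 x individuals for phased
    diploids).
    """
    if len(sites) == 0:
        raise ParameterError("need at least one lead site")
    case_strings = _hap_strings(case_haps, sites)
    ctrl_strings = _hap_strings(ctrl_haps, sites)
    keys = sorted(set(case_strings) | set(ctrl_strings))
    case_counts = {k: 0 for k in keys}
    ctrl_counts = {k: 0 for k in keys}
    for s in case_strings:
        case_counts[s] += 1
    for s in ctrl_strings:
        ctrl_counts[s] += 1
    df = pd.DataFrame({
        "haplotype": keys,
        "case_count": [case_counts[k] for k in keys],
        "ctrl_count": [ctrl_counts[k] for k in keys],
    })
    df["total"] = df["case_count"] + df["ctrl_count"]
    df = df.sort_values(["total", "haplotype"], ascending=[False, True],
                        kind="stable").reset_index(drop=True)
    return df.drop(columns="total")


def haplotype_or(a: int, b: int, c: int, d: int) -> tuple[float, float, float]:
    """Odds ratio of one haplotype versus all others pooled.

    ``a``/``c`` are the haplotype's case/control counts, ``b``/``d``
    the pooled counts of every other haplotype.  Returns
    ``(OR, ci_low, ci_high)`` with the Woolf 95% interval
    ``exp(ln OR +/- 1.96 sqrt(1/a + 1/b + 1/c + 1/d))``; 0.5 is added
    to every cell when any cell is zero.
    """
    counts = (a, b, c, d)
    if any(x < 0 for x in counts):
        raise ParameterError("haplotype counts must be non-negative")
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        raise UndefinedStatisticError("a margin of the haplotype table is zero")
    if 0 in counts:
        a, b, c, d = (x + 0.5 for x in counts)
    log_or = np.log(a * d / (b * c))
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    zcrit = stats.norm.ppf(0.975)
    return (float(np.exp(log_or)),
            float(np.exp(log_or - zcrit * se)),
            float(np.exp(log_or + zcrit * se)))


def haplotype_table(case_haps, ctrl_haps, sites: Sequence[int]) -> pd.DataFrame:
    """Haplotype enumeration plus per-haplotype OR and 95% CI."""
    df = enumerate_haplotypes(case_haps, ctrl_haps, sites)
    total_case = int(df["case_count"].sum())
    total_ctrl = int(df["ctrl_count"].sum())
    ors, los, his = [], [], []
    for _, row in df.iterrows():
        a = int(row["case_count"])
        c = int(row["ctrl_count"])
        est = haplotype_or(a, total_case - a, c, total_ctrl - c)
        ors.append(est[0])
        los.append(est[1])
        his.append(est[2])
    df["odds_ratio"] = ors
    df["ci_low"] = los
    df["ci_high"] = his
    return df


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, x: int, y: int) -> bool:
        rx, ry = self.find(x), self.find(y)
        if rx == ry:
            return False
        self.parent[ry] = rx
        return True


def hamming_network(haplotypes: Sequence[str],
                    frequencies: Sequence[float] | None = None
                    ) -> list[tuple[str, str, int]]:
    """Minimum spanning tree of haplotypes under Hamming distance.

    Kruskal's algorithm with deterministic tie-breaks: equal-weight
    edges are taken preferring higher-frequency endpoints (descending
    max then min endpoint frequency) and then lexicographic order of
    the string pair.  Returns ``(hap_a, hap_b, distance)`` edges whose
    total weight is minimal over all spanning trees.
    """
    haps = list(haplotypes)
    if len(haps) < 2:
        raise ParameterError("need at least two distinct haplotypes")
    if len(set(haps)) != len(haps):
        raise ParameterError("haplotypes must be distinct")
    lengths = {len(h) for h in haps}
    if len(lengths) != 1:
        raise DataError("all haplotypes must have equal length")
    freq = list(frequencies) if frequencies is not None else [1.0] * len(haps)
    if len(freq) != len(haps):
        raise ParameterError("frequencies must match haplotypes")

    def hamming(x: str, y: str) -> int:
        return sum(cx != cy for cx, cy in zip(x, y))

    edges = []
    for i in range(len(haps)):
        for j in range(i + 1, len(haps)):
            w = hamming(haps[i], haps[j])
            fmax, fmin = max(freq[i], freq[j]), min(freq[i], freq[j])
            pair = tuple(sorted((haps[i], haps[j])))
            edges.append((w, -fmax, -fmin, pair, i, j))
    edges.sort()
    uf = _UnionFind(len(haps))
    out = []
    for w, _, _, pair, i, j in edges:
        if uf.union(i, j):
            out.append((pair[0], pair[1], w))
        if len(out) == len(haps) - 1:
            break
    return out
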