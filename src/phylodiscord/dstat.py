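"""ABBA-BABA D-statistics with block-jackknife Z-scores.

D = (nABBA - nBABA) / (nABBA + nBABA) on outgroup-polarized biallelic site
patterns for a rooted triplet (((P1, P2), P3), O).  Gene flow is called
between P2 and P3 when Z > 3 and D > 0, and between P1 and P3 when Z > 3 and
D < 0.  The standard error comes from a delete-one block jackknife; blocks
default to loci.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import treekit
from .msc_sim import SitePatterns
from .treekit import Tree

Z_THRESHOLD = 3.0


class DStatError(Exception):
    pass


@dataclass(frozen=True)
class TripletPatternCounts:
    """ABBA/BABA/BBAA counts for one ordered triplet plus outgroup."""
    p1: str
    p2: str
    p3: str
    outgroup: str
    n_abba: int
    n_baba: int
    n_bbaa: int
    n_sites_used: int

    def __add__(self, other: "TripletPatternCounts") -> "TripletPatternCounts":
        assert (self.p1, self.p2, self.p3) == (other.p1, other.p2, other.p3)
        return TripletPatternCounts(
            self.p1, self.p2, self.p3, self.outgroup,
            self.n_abba + other.n_abba, self.n_baba + other.n_baba,
            self.n_bbaa + other.n_bbaa, self.n_sites_used + other.n_sites_used)


@dataclass
class DResult:
    p1: str
    p2: str
    p3: str
    n_abba: int
    n_baba: int
    d: float | None
    z: float | None
    p: float | None
    significant: bool
    gene_flow_pair: tuple[str, str] | None
    n_blocks: int = 0


def count_abba_baba(patterns: SitePatterns, p1: str, p2: str, p3: str,
                    outgroup: str) -> TripletPatternCounts:
    """Count polarized patterns: ABBA = (0,1,1), BABA = (1,0,1), BBAA = (1,1,0)."""
    for taxon in (p1, p2, p3, outgroup):
        if taxon not in patterns.taxa:
            raise DStatError(f"taxon {taxon!r} missing from pattern matrix")
    r1, r2, r3 = patterns.row(p1), patterns.row(p2), patterns.row(p3)
    abba = int(((r1 == 0) & (r2 == 1) & (r3 == 1)).sum())
    baba = int(((r1 == 1) & (r2 == 0) & (r3 == 1)).sum())
    bbaa = int(((r1 == 1) & (r2 == 1) & (r3 == 0)).sum())
    return TripletPatternCounts(p1, p2, p3, outgroup, abba, baba, bbaa,
                                n_sites_used=patterns.n_sites)


def d_from_counts(n_abba: int, n_baba: int) -> float | None:
    total = n_abba + n_baba
    if total == 0:
        return None
    return (n_abba - n_baba) / total


def d_with_jackknife(blocks: list[TripletPatternCounts],
                     min_blocks: int = 20) -> DResult:
    """Pooled D with a delete-one block jackknife SE and the sign-rule call."""
    blocks = [b for b in blocks if b.n_abba + b.n_baba + b.n_bbaa > 0]
    if not blocks:
        raise DStatError("no non-empty blocks")
    p1, p2, p3 = blocks[0].p1, blocks[0].p2, blocks[0].p3
    abba = np.array([b.n_abba for b in blocks], dtype=float)
    baba = np.array([b.n_baba for b in blocks], dtype=float)
    tot_abba, tot_baba = abba.sum(), baba.sum()
    d = d_from_counts(int(tot_abba), int(tot_baba))
    if d is None:
        return DResult(p1, p2, p3, 0, 0, None, None, None, False, None,
                       n_blocks=len(blocks))
    if len(blocks) < min_blocks:
        warnings.warn(f"only {len(blocks)} blocks; jackknife SE may be unstable",
                      stacklevel=2)
    nb = len(blocks)
    loo_abba = tot_abba - abba
    loo_baba = tot_baba - baba
    with np.errstate(invalid="ignore", divide="ignore"):
        loo_d = (loo_abba - loo_baba) / (loo_abba + loo_baba)
    loo_d = np.where(np.isfinite(loo_d), loo_d, d)
    se = math.sqrt((nb - 1) / nb * float(((loo_d - loo_d.mean()) ** 2).sum()))
    if se == 0.0:
        z = 0.0 if d == 0 else math.inf
    else:
        z = d / se
    p = float(2.0 * stats.norm.sf(abs(z))) if math.isfinite(z) else 0.0
    significant = abs(z) > Z_THRESHOLD
    pair = None
    if significant:
        pair = (p2, p3) if d > 0 else (p1, p3)
    return DResult(p1, p2, p3, int(tot_abba), int(tot_baba), d, z, p,
                   significant, pair, n_blocks=nb)


def order_triplet(triplet, species_tree: Tree | None):
    """(P1, P2, P3) with the species-tree sister pair as (P1, P2).

    Without a species tree the alphabetically sorted order is used and the
    result should be read as one of the three arbitrary orderings.
    """
    trio = sorted(triplet)
    if species_tree is None:
        return tuple(trio)
    pruned = treekit.prune(species_tree, trio)
    for node in pruned.root.postorder():
        if not node.is_leaf() and len(node.leaf_labels()) == 2:
            pair = sorted(node.leaf_labels())
            rest = next(t for t in trio if t not in pair)
            return pair[0], pair[1], rest
    return tuple(trio)  # unresolved triplet in the species tree


def triplet_scan(pattern_blocks: list[SitePatterns], ingroup, outgroup: str,
                 species_tree: Tree | None = None) -> list[DResult]:
    """One jackknifed DResult per unordered ingroup triplet (C(k,3) of them)."""
    ingroup = sorted(ingroup)
    if len(ingroup) < 3:
        raise DStatError("need at least 3 ingroup taxa")
    results = []
    for trio in itertools.combinations(ingroup, 3):
        p1, p2, p3 = order_triplet(trio, species_tree)
        blocks = [count_abba_baba(block, p1, p2, p3, outgroup)
                  for block in pattern_blocks]
        results.append(d_with_jackknife(blocks))
    return results


def pairwise_mean_abs_d(results: list[DResult], taxa=None):
    """Mean |D| over triplets implicating each species pair as the gene-flow pair.

    Returns ``(display, raw)`` DataFrames: ``display`` zeroes out pairs that
    were never significant (the figure-style convention), ``raw`` keeps the
    mean |D| over all triplets where the pair was the candidate gene-flow pair.
    """
    if taxa is None:
        taxa = sorted({t for r in results for t in (r.p1, r.p2, r.p3)})
    acc_all: dict[frozenset, list] = {}
    acc_sig: dict[frozenset, list] = {}
    for r in results:
        if r.d is None:
            continue
        # candidate pair by the sign rule irrespective of significance
        pair = frozenset((r.p2, r.p3) if r.d >= 0 else (r.p1, r.p3))
        acc_all.setdefault(pair, []).append(abs(r.d))
        if r.significant:
            acc_sig.setdefault(pair, []).append(abs(r.d))
    display = pd.DataFrame(0.0, index=taxa, columns=taxa)
    raw = pd.DataFrame(0.0, index=taxa, columns=taxa)
    for pair, values in acc_all.items():
        a, b = sorted(pair)
        raw.loc[a, b] = raw.loc[b, a] = float(np.mean(values))
    for pair, values in acc_sig.items():
        a, b = sorted(pair)
        display.loc[a, b] = display.loc[b, a] = float(np.mean(values))
    return display, raw


def results_to_frame(results: list[DResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append({
            "P1": r.p1, "P2": r.p2, "P3": r.p3,
            "nABBA": r.n_abba, "nBABA": r.n_baba,
            "D": r.d, "Z": r.z, "P": r.p,
            "call": "-".join(r.gene_flow_pair) if r.gene_flow_pair else "none",
        })
    return pd.DataFrame(rows)
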