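"""Quartet scores, concordance factors, polytomy test, reference mapping with ICA,
and an exhaustive quartet-score species-tree search for small taxon sets."""

from __future__ import annotations

import itertools
import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import treekit
from .msc_sim import Alignment, GeneTreeSet
from .treekit import Bipartition, Tree, TreeError


class ConcordanceError(Exception):
    pass


# ---------------------------------------------------------------------------
# Quartet machinery
# ---------------------------------------------------------------------------

def quartet_resolution(tree_bips: set[Bipartition], quartet: frozenset) -> frozenset | None:
    """Sister pair (one side of the induced quartet split) or None if unresolved."""
    for bip in tree_bips:
        in1 = quartet & bip.side1
        if len(in1) == 2 and len(quartet & bip.side2) == 2:
            return frozenset(in1)
    return None


def all_quartet_resolutions(tree: Tree) -> dict[frozenset, frozenset]:
    """Resolution of every 4-taxon subset induced by a tree (unresolved omitted)."""
    bips = treekit.bipartitions(tree)
    labels = sorted(tree.leaf_labels())
    out = {}
    for quad in itertools.combinations(labels, 4):
        q = frozenset(quad)
        res = quartet_resolution(bips, q)
        if res is not None:
            out[q] = res
    return out


@dataclass
class _BranchSets:
    """The four leaf-sets adjacent to an internal species-tree branch."""
    bipartition: Bipartition
    below: tuple[frozenset, frozenset]   # A1, A2 (children side)
    above: tuple[frozenset, frozenset]   # B1, B2 (rest of the tree)


def _branch_adjacent_sets(species_tree: Tree) -> list[_BranchSets]:
    all_leaves = species_tree.leaf_labels()
    n = len(all_leaves)
    out = []
    root = species_tree.root
    for node in root.postorder():
        if node.is_leaf() or node is root:
            continue
        if len(node.children) != 2:
            continue  # polytomies skipped with note at caller level
        clade = node.leaf_labels()
        if not (2 <= len(clade) <= n - 2):
            continue
        a1, a2 = (frozenset(c.leaf_labels()) for c in node.children)
        parent = node.parent
        if parent is root and len(root.children) == 2:
            sibling = next(c for c in root.children if c is not node)
            if sibling.is_leaf() or len(sibling.children) != 2:
                continue
            b1, b2 = (frozenset(c.leaf_labels()) for c in sibling.children)
        else:
            siblings = [frozenset(c.leaf_labels()) for c in parent.children if c is not node]
            rest = all_leaves - frozenset(parent.leaf_labels())
            sets = siblings + ([rest] if rest else [])
            if len(sets) != 2:
                continue
            b1, b2 = sets
        # canonical ordering for deterministic alternative labeling
        a1, a2 = sorted((a1, a2), key=min)
        b1, b2 = sorted((b1, b2), key=min)
        out.append(_BranchSets(Bipartition(clade, all_leaves - clade),
                               below=(a1, a2), above=(b1, b2)))
    return out


@dataclass
class BranchConcordance:
    """Per-branch discordance summary for one internal species-tree branch."""
    bipartition: Bipartition
    q1: float
    q2: float
    q3: float
    n1: int = 0            # decisive gene trees per resolution
    n2: int = 0
    n3: int = 0
    gCF: float | None = None
    sCF: float | None = None
    chi2: float | None = None
    p_polytomy: float | None = None
    concordant: int = 0
    conflict_main: int = 0
    conflict_other: int = 0
    uninformative: int = 0
    ica: float | None = None

    @property
    def decisive(self) -> int:
        return self.n1 + self.n2 + self.n3


def _alternative_bipartitions(bs: _BranchSets) -> tuple[Bipartition, Bipartition]:
    a1, a2 = bs.below
    b1, b2 = bs.above
    alt2_side = a1 | b1
    alt3_side = a1 | b2
    full = a1 | a2 | b1 | b2
    return (Bipartition(alt2_side, full - alt2_side),
            Bipartition(alt3_side, full - alt3_side))


def quartet_scores(species_tree: Tree, trees) -> dict[Bipartition, tuple[float, float, float]]:
    """Proportions of gene-tree quartets supporting each resolution, per branch.

    Quartets draw one taxon from each of the four branch-adjacent subtree sets;
    every gene tree votes with its induced resolution for every such quartet.
    """
    branch_sets = _branch_adjacent_sets(species_tree)
    resolutions = [all_quartet_resolutions(t) for t in trees]
    out = {}
    for bs in branch_sets:
        a1, a2 = bs.below
        b1, b2 = bs.above
        votes = [0, 0, 0]
        for x, y, z, w in itertools.product(sorted(a1), sorted(a2), sorted(b1), sorted(b2)):
            q = frozenset((x, y, z, w))
            for res_map in resolutions:
                res = res_map.get(q)
                if res is None:
                    continue
                if res in (frozenset((x, y)), frozenset((z, w))):
                    votes[0] += 1
                elif res in (frozenset((x, z)), frozenset((y, w))):
                    votes[1] += 1
                else:
                    votes[2] += 1
        total = sum(votes)
        if total == 0:
            continue
        out[bs.bipartition] = tuple(v / total for v in votes)
    return out


def _gene_counts(bs: _BranchSets, tree_bip_sets: list[set[Bipartition]]):
    """(n1, n2, n3): decisive gene trees containing the branch split or one of
    the two block-respecting (NNI) alternatives."""
    alt2, alt3 = _alternative_bipartitions(bs)
    ref = bs.bipartition
    n = [0, 0, 0]
    for bips in tree_bip_sets:
        if ref in bips:
            n[0] += 1
        elif alt2 in bips:
            n[1] += 1
        elif alt3 in bips:
            n[2] += 1
    return tuple(n)


def gene_concordance_factor(species_tree: Tree, trees) -> dict[Bipartition, float | None]:
    """gCF = 100 x (decisive trees containing the split) / (decisive trees)."""
    tree_bip_sets = [treekit.bipartitions(t) for t in trees]
    out = {}
    for bs in _branch_adjacent_sets(species_tree):
        n1, n2, n3 = _gene_counts(bs, tree_bip_sets)
        total = n1 + n2 + n3
        out[bs.bipartition] = 100.0 * n1 / total if total else None
    return out


def polytomy_test(counts) -> tuple[float, int, float]:
    """Pearson chi-square against equal expected frequencies N/3 (df = 2)."""
    n1, n2, n3 = counts
    total = n1 + n2 + n3
    if total <= 0:
        raise ConcordanceError("all-zero counts")
    expected = total / 3.0
    chi2 = sum((c - expected) ** 2 / expected for c in (n1, n2, n3))
    p = float(stats.chi2.sf(chi2, df=2))
    return chi2, 2, p


def collapse_low_support(tree: Tree, cutoff: float) -> Tree:
    """Contract internal branches with support below the cutoff into polytomies."""
    work = tree.copy()
    changed = True
    while changed:
        changed = False
        for node in list(work.root.postorder()):
            if node.is_leaf() or node is work.root:
                continue
            if node.support is not None and node.support < cutoff:
                parent = node.parent
                idx = parent.children.index(node)
                parent.children.pop(idx)
                for child in node.children:
                    child.parent = parent
                    parent.children.append(child)
                changed = True
                break
    return work


# ---------------------------------------------------------------------------
# Site concordance factor
# ---------------------------------------------------------------------------

def site_concordance_factor(species_tree: Tree, alignment: Alignment,
                            n_quartets: int = 100, seed: int = 0
                            ) -> dict[Bipartition, float | None]:
    """Mean percentage of quartet-decisive sites supporting each branch.

    For each branch, ``n_quartets`` random quartets are drawn (one taxon per
    adjacent set); a site is decisive for a quartet when it shows exactly two
    states, twice each, across the four taxa.
    """
    rng = np.random.default_rng(seed)
    idx = {t: i for i, t in enumerate(alignment.taxa)}
    mat = alignment.matrix
    out = {}
    for bs in _branch_adjacent_sets(species_tree):
        sets = [sorted(s) for s in (*bs.below, *bs.above)]
        per_quartet = []
        for _ in range(n_quartets):
            a, b, c, d = (s[rng.integers(len(s))] for s in sets)
            rows = mat[[idx[a], idx[b], idx[c], idx[d]]]
            ok = (rows < 4).all(axis=0)
            r = rows[:, ok]
            m_ref = (r[0] == r[1]) & (r[2] == r[3]) & (r[0] != r[2])
            m_alt1 = (r[0] == r[2]) & (r[1] == r[3]) & (r[0] != r[1])
            m_alt2 = (r[0] == r[3]) & (r[1] == r[2]) & (r[0] != r[1])
            decisive = int(m_ref.sum() + m_alt1.sum() + m_alt2.sum())
            if decisive:
                per_quartet.append(100.0 * float(m_ref.sum()) / decisive)
        out[bs.bipartition] = float(np.mean(per_quartet)) if per_quartet else None
    return out


# ---------------------------------------------------------------------------
# PhyParts-style reference mapping + ICA
# ---------------------------------------------------------------------------

def _bipartitions_with_support(tree: Tree) -> dict[Bipartition, float | None]:
    all_leaves = tree.leaf_labels()
    n = len(all_leaves)
    out = {}
    for node in tree.root.postorder():
        if node is tree.root or node.is_leaf():
            continue
        clade = node.leaf_labels()
        if 2 <= len(clade) <= n - 2:
            bip = Bipartition(clade, all_leaves - clade)
            sup = node.support
            if bip not in out or (sup is not None and (out[bip] is None or out[bip] < sup)):
                out[bip] = sup
    return out


@dataclass
class PhypartsBranch:
    bipartition: Bipartition
    concordant: int
    conflict_main: int
    conflict_other: int
    uninformative: int
    ica: float
    main_alternative: Bipartition | None
    flagged: bool = False  # reference split absent from every informative tree


def phyparts_map(reference: Tree, trees, support_cutoff: float | None = 80.0,
                 min_class_freq: float = 0.05) -> dict[Bipartition, PhypartsBranch]:
    """Classify each gene tree against each reference branch and compute ICA.

    Gene-tree branches with support below the cutoff are ignored (the tree is
    uninformative for a reference branch it can then neither confirm nor
    contradict).  ICA uses log base k over the k observed bipartition classes,
    dropping classes rarer than ``min_class_freq`` among informative trees.
    """
    ref_bips = treekit.bipartitions(reference)
    gene_bips = []
    for tree in trees:
        with_sup = _bipartitions_with_support(tree)
        if support_cutoff is not None:
            with_sup = {b: s for b, s in with_sup.items()
                        if s is None or s >= support_cutoff}
        gene_bips.append(with_sup)

    out = {}
    for ref in ref_bips:
        concordant = 0
        uninformative = 0
        conflict_counter: Counter = Counter()
        for with_sup in gene_bips:
            if ref in with_sup:
                concordant += 1
                continue
            conflicting = [b for b in with_sup if b.taxa == ref.taxa and b.conflicts_with(ref)]
            if not conflicting:
                uninformative += 1
                continue
            best = max(conflicting,
                       key=lambda b: (with_sup[b] if with_sup[b] is not None else -1.0, str(b)))
            conflict_counter[best] += 1
        informative = concordant + sum(conflict_counter.values())
        if informative == 0:
            out[ref] = PhypartsBranch(ref, 0, 0, 0, uninformative, ica=0.0,
                                      main_alternative=None, flagged=True)
            continue
        freqs = {ref: concordant / informative}
        for bip, cnt in conflict_counter.items():
            freqs[bip] = cnt / informative
        kept = {b: f for b, f in freqs.items()
                if f >= min_class_freq or (b == ref and f > 0)}
        norm = sum(kept.values())
        k = len(kept)
        if k <= 1:
            ica = 1.0
        else:
            ica = 1.0 + sum((f / norm) * math.log(f / norm, k)
                            for f in kept.values() if f > 0)
        main_alt = None
        if conflict_counter:
            top = max(conflict_counter.values())
            main_alt = min((b for b, c in conflict_counter.items() if c == top), key=str)
        conflict_main = conflict_counter[main_alt] if main_alt is not None else 0
        conflict_other = sum(conflict_counter.values()) - conflict_main
        out[ref] = PhypartsBranch(ref, concordant, conflict_main, conflict_other,
                                  uninformative, ica=ica, main_alternative=main_alt,
                                  flagged=concordant == 0)
    return out


# ---------------------------------------------------------------------------
# Exhaustive quartet-score species tree search
# ---------------------------------------------------------------------------

def exhaustive_species_tree(trees, outgroup: str):
    """Best rooted topology by total induced-quartet agreement with the gene trees.

    Returns ``(best_topology_id, best_score, tied_ids)``; ties are resolved to
    the lexicographically smallest ID.
    """
    tree_list = list(trees)
    if not tree_list:
        raise ConcordanceError("no gene trees")
    taxa = tree_list[0].leaf_labels()
    ingroup = sorted(taxa - {outgroup})
    if len(ingroup) > 7:
        raise ConcordanceError(f"{len(ingroup)} ingroup taxa: exhaustive search limited to 7")
    vote_counter: Counter = Counter()
    for tree in tree_list:
        for q, res in all_quartet_resolutions(tree).items():
            vote_counter[(q, res)] += 1
    scores = {}
    for topo_id in treekit.enumerate_rooted_topologies(ingroup):
        candidate = treekit.parse_newick(f"({topo_id},{outgroup});")
        score = 0
        for q, res in all_quartet_resolutions(candidate).items():
            score += vote_counter[(q, res)]
        scores[topo_id] = score
    best_score = max(scores.values())
    tied = sorted(t for t, s in scores.items() if s == best_score)
    return tied[0], best_score, tied


# ---------------------------------------------------------------------------
# Combined per-branch report
# ---------------------------------------------------------------------------

def branch_concordance_table(species_tree: Tree, trees,
                             alignment: Alignment | None = None,
                             n_quartets: int = 100, seed: int = 0,
                             support_cutoff: float | None = 80.0) -> pd.DataFrame:
    """One row per internal species-tree branch with q1-q3, gCF, sCF, the
    polytomy test on decisive-tree counts, PhyParts classification and ICA."""
    tree_list = list(trees)
    branch_sets = _branch_adjacent_sets(species_tree)
    qs = quartet_scores(species_tree, tree_list)
    tree_bip_sets = [treekit.bipartitions(t) for t in tree_list]
    scf = (site_concordance_factor(species_tree, alignment, n_quartets, seed)
           if alignment is not None else {})
    pp = phyparts_map(species_tree, tree_list, support_cutoff=support_cutoff)
    rows = []
    for bs in branch_sets:
        bip = bs.bipartition
        n1, n2, n3 = _gene_counts(bs, tree_bip_sets)
        total = n1 + n2 + n3
        q = qs.get(bip, (float("nan"),) * 3)
        chi2 = p_poly = None
        if total:
            chi2, _, p_poly = polytomy_test((n1, n2, n3))
        branch_pp = pp.get(bip)
        rows.append({
            "branch": str(bip),
            "q1": q[0], "q2": q[1], "q3": q[2],
            "n1": n1, "n2": n2, "n3": n3,
            "gCF": 100.0 * n1 / total if total else None,
            "sCF": scf.get(bip),
            "chi2": chi2, "p_polytomy": p_poly,
            "concordant": branch_pp.concordant if branch_pp else None,
            "conflict_main": branch_pp.conflict_main if branch_pp else None,
            "conflict_other": branch_pp.conflict_other if branch_pp else None,
            "uninformative": branch_pp.uninformative if branch_pp else None,
            "ICA": branch_pp.ica if branch_pp else None,
        })
    return pd.DataFrame(rows)
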