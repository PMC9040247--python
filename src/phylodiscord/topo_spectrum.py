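"""Classify gene trees into canonical topologies and build frequency spectra."""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from . import treekit
from .msc_sim import GeneTreeSet
from .treekit import Tree, TreeError


class SpectrumError(Exception):
    pass


def classify_topology(tree: Tree, outgroup: str) -> str | None:
    """Canonical topology ID, or None for unresolved (polytomous) trees.

    Raises :class:`TreeError` listing absent taxa if the outgroup is missing.
    """
    if outgroup not in tree.leaf_labels():
        raise TreeError(f"missing taxa: {outgroup}")
    rooted = treekit.reroot_on_outgroup(tree, outgroup)
    if rooted.has_polytomy():
        return None
    return treekit.canonical_topology_id(tree, outgroup)


@dataclass
class TopologySpectrum:
    """Counts and frequencies per topology over the full enumerated universe."""
    counts: dict[str, int]
    total: int
    unresolved: int = 0
    ranks: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if not self.ranks:
            # rank by count desc, ties broken lexicographically by topology ID
            ordered = sorted(self.counts, key=lambda t: (-self.counts[t], t))
            self.ranks = {t: i + 1 for i, t in enumerate(ordered)}

    def frequency(self, topology_id: str) -> float:
        return self.counts.get(topology_id, 0) / self.total

    @property
    def frequencies(self) -> dict[str, float]:
        return {t: c / self.total for t, c in self.counts.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [{"topology_id": t, "rank": self.ranks[t], "count": c,
                 "frequency": c / self.total}
                for t, c in self.counts.items()]
        return (pd.DataFrame(rows)
                .sort_values("rank")
                .reset_index(drop=True))

    def __add__(self, other: "TopologySpectrum") -> "TopologySpectrum":
        merged = Counter(self.counts)
        merged.update(other.counts)
        return TopologySpectrum(counts=dict(merged), total=self.total + other.total,
                                unresolved=self.unresolved + other.unresolved)


def topology_spectrum(trees: GeneTreeSet | list[Tree], outgroup: str,
                      ingroup: set[str] | None = None) -> TopologySpectrum:
    """Spectrum over the full topology universe (zero rows included).

    Unresolved trees are excluded from the denominator and reported separately.
    """
    tree_list = list(trees)
    if not tree_list:
        raise SpectrumError("no trees supplied")
    if ingroup is None:
        ingroup = set(tree_list[0].leaf_labels()) - {outgroup}
    universe = treekit.enumerate_rooted_topologies(ingroup)
    counts = {t: 0 for t in universe}
    unresolved = 0
    classified = 0
    for tree in tree_list:
        topo = classify_topology(tree, outgroup)
        if topo is None:
            unresolved += 1
            continue
        if topo not in counts:
            raise SpectrumError(f"topology {topo} outside the enumerated universe "
                                f"(taxon set mismatch?)")
        counts[topo] += 1
        classified += 1
    if classified == 0:
        raise SpectrumError("zero classifiable trees")
    return TopologySpectrum(counts=counts, total=classified, unresolved=unresolved)
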