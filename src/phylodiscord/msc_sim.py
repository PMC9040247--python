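"""Synthetic-data generator: multispecies coalescent with introgression pulses.

Gene trees are simulated backward in time inside a dated species tree.  Within
each species branch, ``k`` lineages coalesce at total rate ``k(k-1)/2`` per
coalescent unit; a pulse ``(donor, recipient, time, gamma)`` moves each lineage
present in the recipient branch to the donor with probability ``gamma``
(independently per lineage), which is the backward-time reading of an
instantaneous unidirectional admixture event with inheritance probability
``gamma``.  Species-tree times are in arbitrary time units; ``coal_scale``
(time units per coalescent unit) converts them to coalescent units.

Each gene-tree edge records the ``(species_branch, duration)`` segments it
traverses, so lineage-rate scaling can apply clade-specific multipliers after
the fact (pulse-transferred segments naturally pick up the donor clade's rate).
"""

from __future__ import annotations

import dataclasses
import hashlib
import math
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import treekit
from .treekit import Node, Tree

ROOT_BRANCH = "__root__"

NUC = np.array(["A", "C", "G", "T"])


class ScenarioError(Exception):
    """Invalid simulation scenario."""


class NoClosedFormError(Exception):
    """Raised when no analytic topology-frequency expression is available."""


@dataclass(frozen=True)
class Pulse:
    """Instantaneous introgression: recipient inherits from donor with probability gamma."""
    donor: str
    recipient: str
    time: float
    gamma: float


@dataclass(frozen=True)
class RateSpec:
    """Clade rate multiplier: branches whose tips are a subset of ``tips`` get rate ``r``."""
    tips: frozenset
    r: float
    name: str = ""


@dataclass
class Scenario:
    """Full description of one synthetic dataset."""
    species_tree: Tree          # branch lengths = durations in time units, ultrametric
    outgroup: str | None = None
    pulses: list[Pulse] = field(default_factory=list)
    rates: list[RateSpec] = field(default_factory=list)
    mu: float = 1e-3            # substitutions / site / time unit
    coal_scale: float = 1.0     # time units per coalescent unit
    loci: int = 100
    length: int = 300
    seed: int = 0
    model: str = "JC69"
    kappa: float = 2.0

    def __post_init__(self):
        self.validate()

    # -- derived structure ------------------------------------------------
    def branch_table(self) -> dict[str, tuple[float, float]]:
        """branch key -> (child-node time, parent-node time) in time units."""
        times = node_times(self.species_tree)
        table = {}
        for node in self.species_tree.root.postorder():
            if node is self.species_tree.root:
                continue
            key = branch_key(node)
            table[key] = (times[id(node)], times[id(node.parent)])
        root_time = times[id(self.species_tree.root)]
        table[ROOT_BRANCH] = (root_time, math.inf)
        return table

    def validate(self) -> None:
        if self.mu < 0:
            raise ScenarioError("mu must be >= 0")
        if self.coal_scale <= 0:
            raise ScenarioError("coal_scale must be > 0")
        if self.loci < 1 or self.length < 1:
            raise ScenarioError("loci and length must be positive")
        for node in self.species_tree.root.postorder():
            if node is not self.species_tree.root and node.length is None:
                raise ScenarioError("species tree must have branch lengths (durations)")
        table = self.branch_table()
        for pulse in self.pulses:
            if not (0.0 <= pulse.gamma <= 1.0):
                raise ScenarioError(f"gamma {pulse.gamma} outside [0, 1]")
            for role, key in (("donor", pulse.donor), ("recipient", pulse.recipient)):
                if key not in table:
                    raise ScenarioError(f"pulse {role} branch {key!r} not in species tree")
                lo, hi = table[key]
                if not (lo <= pulse.time < hi):
                    raise ScenarioError(
                        f"pulse time {pulse.time} outside lifespan [{lo}, {hi}) of {role} {key!r}")
        for spec in self.rates:
            if spec.r <= 0:
                raise ScenarioError("rate multipliers must be > 0")
            if not spec.tips <= self.species_tree.leaf_labels():
                raise ScenarioError(f"rate clade {sorted(spec.tips)} not a subset of tips")

    def rate_for_branch(self, key: str) -> float:
        """Clade multiplier for a species branch; most specific (smallest) clade wins."""
        if key == ROOT_BRANCH:
            return 1.0
        tips = frozenset(key.split(","))
        best = None
        for spec in self.rates:
            if tips <= spec.tips and (best is None or len(spec.tips) < len(best.tips)):
                best = spec
        return best.r if best is not None else 1.0

    def content_hash(self) -> str:
        payload = repr((treekit.write_newick(self.species_tree, canonical=True),
                        self.outgroup, sorted(map(repr, self.pulses)),
                        sorted((sorted(s.tips), s.r) for s in self.rates),
                        self.mu, self.coal_scale, self.loci, self.length,
                        self.seed, self.model, self.kappa))
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def branch_key(node: Node) -> str:
    return ",".join(sorted(node.leaf_labels()))


def node_times(tree: Tree, tol: float = 1e-6) -> dict[int, float]:
    """Node times (tips at 0) for an ultrametric-in-time species tree."""
    times: dict[int, float] = {}
    for node in tree.root.postorder():
        if node.is_leaf():
            times[id(node)] = 0.0
        else:
            cand = [times[id(c)] + (c.length or 0.0) for c in node.children]
            if max(cand) - min(cand) > tol * max(1.0, max(cand)):
                raise ScenarioError(
                    f"species tree not ultrametric in time at clade {branch_key(node)}: {cand}")
            times[id(node)] = sum(cand) / len(cand)
    return times


# ---------------------------------------------------------------------------
# Scenario (de)serialization
# ---------------------------------------------------------------------------

def scenario_to_dict(sc: Scenario) -> dict:
    return {
        "species_tree": treekit.write_newick(sc.species_tree, canonical=True),
        "outgroup": sc.outgroup,
        "pulses": [{"donor": p.donor, "recipient": p.recipient,
                    "time": p.time, "gamma": p.gamma} for p in sc.pulses],
        "rates": [{"tips": sorted(s.tips), "r": s.r, "name": s.name} for s in sc.rates],
        "mu": sc.mu, "coal_scale": sc.coal_scale, "loci": sc.loci,
        "length": sc.length, "seed": sc.seed, "model": sc.model, "kappa": sc.kappa,
    }


def scenario_from_dict(d: dict) -> Scenario:
    return Scenario(
        species_tree=treekit.parse_newick(d["species_tree"], unit="time"),
        outgroup=d.get("outgroup"),
        pulses=[Pulse(p["donor"], p["recipient"], float(p["time"]), float(p["gamma"]))
                for p in d.get("pulses", [])],
        rates=[RateSpec(frozenset(s["tips"]), float(s["r"]), s.get("name", ""))
               for s in d.get("rates", [])],
        mu=float(d.get("mu", 1e-3)),
        coal_scale=float(d.get("coal_scale", 1.0)),
        loci=int(d.get("loci", 100)),
        length=int(d.get("length", 300)),
        seed=int(d.get("seed", 0)),
        model=d.get("model", "JC69"),
        kappa=float(d.get("kappa", 2.0)),
    )


def load_scenario(path) -> Scenario:
    with open(path) as fh:
        return scenario_from_dict(yaml.safe_load(fh))


def save_scenario(sc: Scenario, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(scenario_to_dict(sc), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Default scenarios emulating the study design
# ---------------------------------------------------------------------------

def tribe_level_scenario(**overrides) -> Scenario:
    """Five ingroup taxa + outgroup, 2608 loci, one gamma=0.73 pulse, one fast clade."""
    newick = ("(((((T5:52.47,T4:52.47):2.63,T3:55.1):2.7,T2:57.8):2.71,T1:60.51):2.08,"
              "OUT:62.59);")
    base = dict(
        species_tree=treekit.parse_newick(newick, unit="time"),
        outgroup="OUT",
        pulses=[Pulse(donor="T3", recipient="T5", time=52.0, gamma=0.73)],
        rates=[RateSpec(frozenset({"T4"}), 5.58123, name="fast")],
        mu=1e-3, coal_scale=4.0, loci=2608, length=300, seed=0,
    )
    base.update(overrides)
    return Scenario(**base)


def subtribe_level_scenario(**overrides) -> Scenario:
    """Four ingroup taxa + outgroup, 1865 loci, mostly-ILS regime."""
    newick = ("((((S4:39.43,S3:39.43):3.1,S2:42.53):4.13,S1:46.66):8.44,OUT:55.1);")
    base = dict(
        species_tree=treekit.parse_newick(newick, unit="time"),
        outgroup="OUT",
        pulses=[Pulse(donor="S2", recipient="S4", time=30.0, gamma=0.1)],
        rates=[],
        mu=1e-3, coal_scale=4.0, loci=1865, length=300, seed=0,
    )
    base.update(overrides)
    return Scenario(**base)


# ---------------------------------------------------------------------------
# Gene tree simulation
# ---------------------------------------------------------------------------

@dataclass
class GeneTreeSet:
    """Homogeneous collection of gene trees plus provenance."""
    trees: list[Tree]
    unit: str
    scenario_hash: str = ""
    seed: int = 0

    def __len__(self):
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)

    def content_hash(self) -> str:
        h = hashlib.sha256()
        for tree in self.trees:
            h.update(treekit.write_newick(tree, canonical=True).encode())
        return h.hexdigest()[:16]


class _Lineage:
    __slots__ = ("node", "segments", "seg_start", "branch")

    def __init__(self, node, branch, time):
        self.node = node
        self.segments: list[tuple[str, float]] = []
        self.seg_start = time
        self.branch = branch

    def move(self, new_branch: str, time: float):
        self.segments.append((self.branch, time - self.seg_start))
        self.branch = new_branch
        self.seg_start = time


def _simulate_locus(sc: Scenario, rng: np.random.Generator) -> Tree:
    sp = sc.species_tree
    times = node_times(sp)
    # events sorted by time: pulses first at equal times, then speciation merges
    events: list[tuple[float, int, object]] = []
    for pulse in sc.pulses:
        events.append((pulse.time, 0, pulse))
    for node in sp.root.postorder():
        if not node.is_leaf():
            events.append((times[id(node)], 1, node))
    events.sort(key=lambda e: (e[0], e[1]))

    active: dict[str, list[_Lineage]] = {}
    node_time: dict[int, float] = {}
    for leaf in sp.root.leaves():
        gnode = Node(leaf.label)
        node_time[id(gnode)] = 0.0
        active[branch_key(leaf)] = [_Lineage(gnode, branch_key(leaf), 0.0)]

    def coalesce_within(branch: str, t0: float, t1: float):
        lineages = active[branch]
        t = t0
        while len(lineages) > 1:
            k = len(lineages)
            rate = k * (k - 1) / 2.0 / sc.coal_scale
            t = t + rng.exponential(1.0 / rate)
            if t >= t1:
                return
            i, j = rng.choice(k, size=2, replace=False)
            a, b = lineages[int(i)], lineages[int(j)]
            parent = Node()
            node_time[id(parent)] = t
            for lin in (a, b):
                lin.move(branch, t)  # close final segment
                lin.node.length = t - node_time[id(lin.node)]
                lin.node.segments = lin.segments
                parent.add_child(lin.node)
            lineages[:] = [l for l in lineages if l is not a and l is not b]
            lineages.append(_Lineage(parent, branch, t))

    current = 0.0
    for etime, _, payload in events:
        for branch in list(active):
            if len(active[branch]) > 1:
                coalesce_within(branch, current, etime)
        if isinstance(payload, Pulse):
            if payload.recipient in active:
                moved = []
                for lin in list(active[payload.recipient]):
                    if rng.random() < payload.gamma:
                        lin.move(payload.donor, etime)
                        active[payload.recipient].remove(lin)
                        moved.append(lin)
                if moved:
                    active.setdefault(payload.donor, []).extend(moved)
        else:  # speciation node: child branches merge into the parent branch
            sp_node = payload
            parent_key = ROOT_BRANCH if sp_node is sp.root else branch_key(sp_node)
            pool = active.setdefault(parent_key, [])
            for child in sp_node.children:
                key = branch_key(child)
                for lin in active.pop(key, []):
                    lin.move(parent_key, etime)
                    pool.append(lin)
        current = etime

    coalesce_within(ROOT_BRANCH, current, math.inf)
    root_lin = active[ROOT_BRANCH][0]
    root_lin.segments.append((root_lin.branch, 0.0))
    root = root_lin.node
    root.segments = None
    # convert stored lengths (time units) to coalescent units
    for node in root.postorder():
        if node is not root and node.length is not None:
            node.length = node.length / sc.coal_scale
    return Tree(root, unit="coalescent", validate=False)


def simulate_gene_trees(scenario: Scenario) -> GeneTreeSet:
    """One coalescent gene tree per locus; RNG streams are split per locus so
    locus ``i`` is invariant to the total locus count."""
    scenario.validate()
    streams = np.random.SeedSequence(scenario.seed).spawn(scenario.loci)
    trees = [_simulate_locus(scenario, np.random.default_rng(s)) for s in streams]
    return GeneTreeSet(trees=trees, unit="coalescent",
                       scenario_hash=scenario.content_hash(), seed=scenario.seed)


def scale_branch_lengths(trees: GeneTreeSet, scenario: Scenario) -> GeneTreeSet:
    """Convert to substitutions/site: each traversed segment is scaled by
    mu times the rate multiplier of the species-tree clade it lies in."""
    scaled = []
    for tree in trees:
        dup = tree.copy()
        for node in dup.root.postorder():
            if node is dup.root:
                node.length = None
                continue
            if node.segments is None:
                raise ScenarioError("gene tree lacks segment records; "
                                    "was it produced by simulate_gene_trees?")
            node.length = sum(scenario.mu * scenario.rate_for_branch(b) * dt
                              for b, dt in node.segments)
        dup.unit = "subs/site"
        scaled.append(dup)
    return GeneTreeSet(trees=scaled, unit="subs/site",
                       scenario_hash=trees.scenario_hash, seed=trees.seed)


# ---------------------------------------------------------------------------
# Sequence simulation
# ---------------------------------------------------------------------------

@dataclass
class Alignment:
    """Aligned sequences: ``matrix[i, j]`` is the state code of taxon i at site j.

    Codes 0..3 = A, C, G, T; 4 = gap/ambiguity.
    """
    taxa: list[str]
    matrix: np.ndarray  # (ntaxa, nsites) uint8

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    def row(self, label: str) -> np.ndarray:
        return self.matrix[self.taxa.index(label)]

    def sequence(self, label: str) -> str:
        codes = self.row(label)
        chars = np.where(codes < 4, NUC[np.minimum(codes, 3)], "-")
        return "".join(chars)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for label in self.taxa:
                fh.write(f">{label}\n{self.sequence(label)}\n")

    @classmethod
    def from_fasta(cls, path) -> "Alignment":
        taxa, rows = [], []
        label, chunks = None, []
        code = np.full(256, 4, dtype=np.uint8)
        for i, ch in enumerate("ACGT"):
            code[ord(ch)] = i
            code[ord(ch.lower())] = i
        with open(path) as fh:
            for line in fh:
                line = line.rstrip()
                if line.startswith(">"):
                    if label is not None:
                        taxa.append(label)
                        rows.append(code[np.frombuffer("".join(chunks).encode(), dtype=np.uint8)])
                    label, chunks = line[1:].split()[0], []
                elif line:
                    chunks.append(line)
        if label is not None:
            taxa.append(label)
            rows.append(code[np.frombuffer("".join(chunks).encode(), dtype=np.uint8)])
        lengths = {len(r) for r in rows}
        if len(lengths) != 1:
            raise ValueError("unaligned FASTA: sequences differ in length")
        return cls(taxa=taxa, matrix=np.vstack(rows))

    @classmethod
    def concat(cls, alignments: list["Alignment"]) -> "Alignment":
        taxa = alignments[0].taxa
        mats = []
        for aln in alignments:
            idx = [aln.taxa.index(t) for t in taxa]
            mats.append(aln.matrix[idx])
        return cls(taxa=list(taxa), matrix=np.hstack(mats))


def jc69_matrix(d: float) -> np.ndarray:
    same = 0.25 + 0.75 * math.exp(-4.0 * d / 3.0)
    diff = 0.25 - 0.25 * math.exp(-4.0 * d / 3.0)
    P = np.full((4, 4), diff)
    np.fill_diagonal(P, same)
    return P


def hky_matrix(d: float, kappa: float, freqs: np.ndarray) -> np.ndarray:
    """HKY85 transition probabilities via the rate matrix exponential, scaled so
    that ``d`` is the expected number of substitutions per site."""
    from scipy.linalg import expm
    Q = np.empty((4, 4))
    transitions = {(0, 2), (2, 0), (1, 3), (3, 1)}  # A<->G, C<->T
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            Q[i, j] = (kappa if (i, j) in transitions else 1.0) * freqs[j]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    rate = -(freqs * np.diag(Q)).sum()
    return expm(Q * (d / rate))


def simulate_alignment(tree: Tree, length: int, model: str = "JC69",
                       seed: int | np.random.Generator = 0, kappa: float = 2.0,
                       freqs=None) -> Alignment:
    """I.i.d. sites evolved down the tree; branch lengths are substitutions/site."""
    if length <= 0:
        raise ValueError("alignment length must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    freqs = np.full(4, 0.25) if freqs is None else np.asarray(freqs, dtype=float)
    if model == "JC69":
        pmat = jc69_matrix
    elif model == "HKY":
        def pmat(d):
            return hky_matrix(d, kappa, freqs)
    else:
        raise ValueError(f"unknown substitution model {model!r}")

    states: dict[int, np.ndarray] = {}
    states[id(tree.root)] = rng.choice(4, size=length, p=freqs)
    taxa, rows = [], []
    for node in tree.root.preorder():
        if node is tree.root:
            pass
        else:
            if node.length is None:
                raise ValueError("missing branch length in tree for sequence simulation")
            P = pmat(node.length)
            cum = P.cumsum(axis=1)
            parent_states = states[id(node.parent)]
            draw = rng.random(length)
            states[id(node)] = (draw[:, None] > cum[parent_states]).sum(axis=1).astype(np.uint8)
        if node.is_leaf():
            taxa.append(node.label)
            rows.append(states[id(node)].astype(np.uint8))
    return Alignment(taxa=taxa, matrix=np.vstack(rows))


# ---------------------------------------------------------------------------
# Site patterns
# ---------------------------------------------------------------------------

@dataclass
class SitePatterns:
    """Outgroup-polarized biallelic 0/1 matrix (taxa x sites); 0 = outgroup allele."""
    taxa: list[str]
    matrix: np.ndarray  # (ntaxa, nsites) uint8 in {0, 1}
    n_input_sites: int = 0

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    def row(self, label: str) -> np.ndarray:
        return self.matrix[self.taxa.index(label)]

    def to_tsv(self, path) -> None:
        import pandas as pd
        pd.DataFrame(self.matrix, index=self.taxa).to_csv(path, sep="\t", header=False)

    @classmethod
    def from_tsv(cls, path) -> "SitePatterns":
        import pandas as pd
        df = pd.read_csv(path, sep="\t", header=None, index_col=0)
        return cls(taxa=list(df.index), matrix=df.to_numpy(dtype=np.uint8),
                   n_input_sites=df.shape[1])


def extract_site_patterns(alignment: Alignment, outgroup: str) -> SitePatterns:
    """Keep biallelic gap-free columns, polarized so the outgroup allele is 0."""
    import warnings
    if outgroup not in alignment.taxa:
        raise ValueError(f"outgroup {outgroup!r} not in alignment")
    mat = alignment.matrix
    clean = (mat < 4).all(axis=0)
    sub = mat[:, clean]
    # biallelic test: exactly two distinct states per column
    n_states = np.zeros(sub.shape[1], dtype=int)
    for s in range(4):
        n_states += (sub == s).any(axis=0)
    keep = n_states == 2
    sub = sub[:, keep]
    anc = sub[alignment.taxa.index(outgroup)]
    out = (sub != anc[None, :]).astype(np.uint8)
    if out.shape[1] == 0:
        warnings.warn("no biallelic sites retained", stacklevel=2)
    return SitePatterns(taxa=list(alignment.taxa), matrix=out,
                        n_input_sites=alignment.n_sites)


# ---------------------------------------------------------------------------
# Analytic expectations
# ---------------------------------------------------------------------------

def _mrca_time(sc: Scenario, a: str, b: str) -> float:
    sp = sc.species_tree
    times = node_times(sp)
    ancestors = set()
    node = sp.find_leaf(a)
    while node is not None:
        ancestors.add(id(node))
        node = node.parent
    node = sp.find_leaf(b)
    while node is not None:
        if id(node) in ancestors:
            return times[id(node)]
        node = node.parent
    raise ScenarioError("disconnected tree")  # pragma: no cover


def _pair_separation_times(sc: Scenario, taxa: tuple[str, str, str]) -> dict[frozenset, float]:
    """Time at which each pair of lineages first shares a species branch (no pulses)."""
    return {frozenset((x, y)): _mrca_time(sc, x, y)
            for x, y in ((taxa[0], taxa[1]), (taxa[0], taxa[2]), (taxa[1], taxa[2]))}


def _triplet_freqs_from_septimes(sep: dict[frozenset, float], coal_scale: float,
                                 taxa: tuple[str, str, str]):
    a, b, c = taxa
    pairs = sorted(sep, key=sep.get)
    inner = pairs[0]
    t_inner = sep[inner]
    t_outer = max(sep.values())
    T = (t_outer - t_inner) / coal_scale
    p_disc = math.exp(-T) / 3.0
    freqs = {}
    for pair in (frozenset((a, b)), frozenset((a, c)), frozenset((b, c))):
        freqs[pair] = (1.0 - 2.0 * p_disc) if pair == inner else p_disc
    return freqs


def expected_topology_freq(scenario: Scenario, triplet) -> dict[frozenset, float]:
    """Analytic topology frequencies for a species triplet.

    Returns a map {sister pair -> probability}.  Without pulses this is the
    standard coalescent expectation: the concordant pair at 1 - (2/3)e^{-T}
    and each discordant resolution at (1/3)e^{-T}, with T the internal branch
    in coalescent units.  A single pulse whose recipient branch contains
    exactly one triplet taxon is handled as a gamma-weighted mixture of the
    moved and unmoved histories; anything else has no closed form here.
    """
    taxa = tuple(triplet)
    if len(taxa) != 3:
        raise ValueError("triplet must have exactly 3 taxa")
    relevant = [p for p in scenario.pulses
                if frozenset(p.recipient.split(",")) & set(taxa)]
    base = _pair_separation_times(scenario, taxa)
    if not relevant:
        return _triplet_freqs_from_septimes(base, scenario.coal_scale, taxa)
    if len(relevant) > 1:
        raise NoClosedFormError("multiple pulses affect this triplet")
    pulse = relevant[0]
    rec_tips = frozenset(pulse.recipient.split(",")) & set(taxa)
    donor_tips = set(pulse.donor.split(","))
    if len(rec_tips) != 1:
        raise NoClosedFormError("pulse recipient must contain exactly one triplet taxon")
    moved_taxon = next(iter(rec_tips))
    if moved_taxon in donor_tips:
        raise NoClosedFormError("donor and recipient clades overlap on the triplet")
    # moved history: the recipient lineage relocates into the donor branch at
    # the pulse time; it then meets taxon y when y's lineage shares a species
    # branch with the donor lineage path (at the pulse itself if y is inside
    # the donor clade, at their MRCA otherwise).
    anchor = next(iter(donor_tips))
    moved = dict(base)
    for other in taxa:
        if other == moved_taxon:
            continue
        if other in donor_tips:
            moved[frozenset((moved_taxon, other))] = pulse.time
        else:
            moved[frozenset((moved_taxon, other))] = _mrca_time(scenario, anchor, other)
    f_base = _triplet_freqs_from_septimes(base, scenario.coal_scale, taxa)
    f_moved = _triplet_freqs_from_septimes(moved, scenario.coal_scale, taxa)
    return {pair: (1 - pulse.gamma) * f_base[pair] + pulse.gamma * f_moved[pair]
            for pair in f_base}
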