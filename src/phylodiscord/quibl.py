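"""Branch-length mixture test separating lineage sorting from introgression.

For each species triplet and each of its three topology classes, the internal
branch lengths collected across gene trees are fit with:

* model 1 (lineage sorting only): t ~ Exponential(lambda);
* model 2 (mixture): t ~ pi * Exp(lambda) + (1 - pi) * [C + Exp(lambda)],
  a shared-rate exponential plus a shifted exponential whose delay C absorbs
  the minimum internal branch implied by a speciation/introgression event.

Models are compared with BIC (k = 1 vs k = 3, N = number of lengths);
dBIC = BIC2 - BIC1 below -10 on a topology discordant with the species tree
is called introgression.  The mixture is fit by EM over (pi, lambda) at fixed
C, profiled over a grid of candidate delays (C = 0 is always included, which
guarantees logL2 >= logL1).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import treekit
from .treekit import Tree

DBIC_CUTOFF = -10.0
MIN_LENGTHS = 30


class QuiblError(Exception):
    pass


@dataclass
class TripletLengths:
    """Internal branch lengths of gene trees showing one triplet topology."""
    triplet: tuple[str, str, str]
    sister_pair: frozenset
    lengths: np.ndarray
    n_zero: int = 0
    n_skipped: int = 0

    @property
    def n(self) -> int:
        return len(self.lengths)


@dataclass
class QuiblFit:
    triplet: tuple[str, str, str]
    sister_pair: frozenset
    n: int
    lambda1: float
    logl1: float
    bic1: float
    pi: float
    lambda2: float
    c: float
    logl2: float
    bic2: float
    dbic: float
    low_power: bool = False
    discordant: bool | None = None

    @property
    def introgression_call(self) -> bool:
        return bool(self.discordant) and self.dbic < DBIC_CUTOFF


# ---------------------------------------------------------------------------
# Length extraction
# ---------------------------------------------------------------------------

def triplet_branch_lengths(trees, triplet, outgroup: str) -> dict[frozenset, TripletLengths]:
    """Prune each gene tree to triplet + outgroup and record, per topology
    class (keyed by sister pair), the single internal branch length."""
    trio = tuple(sorted(triplet))
    classes: dict[frozenset, list] = {
        frozenset(p): [] for p in itertools.combinations(trio, 2)}
    zeros = {k: 0 for k in classes}
    skipped = 0
    for tree in trees:
        pruned = treekit.prune(tree, set(trio) | {outgroup})
        rooted = treekit.reroot_on_outgroup(pruned, outgroup)
        if rooted.has_polytomy():
            skipped += 1
            continue
        ingroup_node = next(c for c in rooted.root.children
                            if not (c.is_leaf() and c.label == outgroup))
        pair_node = next((c for c in ingroup_node.children
                          if not c.is_leaf() and len(c.leaf_labels()) == 2), None)
        if pair_node is None or pair_node.length is None:
            skipped += 1
            continue
        key = frozenset(pair_node.leaf_labels())
        if pair_node.length > 0:
            classes[key].append(pair_node.length)
        else:
            zeros[key] += 1
    return {key: TripletLengths(trio, key, np.asarray(vals, dtype=float),
                                n_zero=zeros[key], n_skipped=skipped)
            for key, vals in classes.items()}


# ---------------------------------------------------------------------------
# Likelihoods and EM
# ---------------------------------------------------------------------------

def _loglik_exp(t: np.ndarray, lam: float) -> float:
    return float(len(t) * math.log(lam) - lam * t.sum())


def mixture_loglik(t: np.ndarray, pi: float, lam: float, c: float) -> float:
    f1 = pi * lam * np.exp(-lam * t)
    f2 = np.where(t >= c, (1.0 - pi) * lam * np.exp(-lam * (t - c)), 0.0)
    dens = f1 + f2
    if np.any(dens <= 0):
        return -math.inf
    return float(np.log(dens).sum())


def _em_fixed_c(t: np.ndarray, c: float, pi0: float, lam0: float,
                tol: float = 1e-8, max_iter: int = 600):
    """EM over (pi, lambda) at a single fixed shift; returns (pi, lambda, logL)."""
    pi, lam, ll = _em_profile(t, np.array([c]), np.array([pi0]), np.array([lam0]),
                              tol=tol, max_iter=max_iter)
    return float(pi[0]), float(lam[0]), float(ll[0])


def _em_profile(t: np.ndarray, cs: np.ndarray, pis: np.ndarray, lams: np.ndarray,
                tol: float = 1e-9, max_iter: int = 600):
    """EM over (pi, lambda), run in parallel for a whole vector of fixed shifts.

    The observed-data log-likelihood is non-decreasing per chain across
    iterations (asserted) — the standard EM guarantee for this mixture.
    Returns arrays (pi, lambda, logL) aligned with ``cs``.
    """
    n = len(t)
    T = t[None, :]
    C = cs[:, None]
    mask = T >= C
    shifted = T - C  # negative entries only ever multiplied by zero weight
    pi = pis.astype(float).copy()
    lam = lams.astype(float).copy()
    prev = np.full(len(cs), -np.inf)
    for _ in range(max_iter):
        f1 = pi[:, None] * lam[:, None] * np.exp(-lam[:, None] * T)
        f2 = (1.0 - pi)[:, None] * lam[:, None] * np.exp(-lam[:, None] * np.maximum(shifted, 0.0))
        f2 = np.where(mask, f2, 0.0)
        dens = f1 + f2
        ll = np.log(dens).sum(axis=1)
        assert np.all(ll >= prev - 1e-7), "EM decreased the log-likelihood"
        done = np.all(np.abs(ll - prev) < tol)
        prev = ll
        if done:
            break
        w = f1 / dens  # responsibility of the unshifted component
        pi = np.clip(w.mean(axis=1), 1e-12, 1.0 - 1e-12)
        scale = (w * T + (1.0 - w) * shifted).sum(axis=1)
        lam = np.where(scale > 0, n / scale, lam)
    return pi, lam, prev


def fit_quibl_models(lengths: TripletLengths, seed: int = 0, n_starts: int = 3,
                     n_c_grid: int = 41, n_refine: int = 12) -> QuiblFit:
    """Fit both models and report BICs; deterministic given the seed.

    The mixture likelihood is profiled over the delay C (coarse quantile grid,
    then a local refinement around the best candidate), with a seeded
    multi-start EM over (pi, lambda) at each C.  C = 0 is always a candidate,
    so logL2 >= logL1 by construction.
    """
    t = np.asarray(lengths.lengths, dtype=float)
    n = len(t)
    if n == 0:
        raise QuiblError("no branch lengths for this topology class")
    if float(t.min()) == float(t.max()):
        raise QuiblError("degenerate data: all internal branch lengths equal")
    low_power = n < MIN_LENGTHS

    lam1 = n / float(t.sum())
    logl1 = _loglik_exp(t, lam1)
    bic1 = -2.0 * logl1 + 1.0 * math.log(n)

    rng = np.random.default_rng(seed)
    qs = np.linspace(0.02, 0.98, n_c_grid)
    candidates = np.unique(np.concatenate([[0.0], np.quantile(t, qs)]))
    # keep C strictly below max(t) so the shifted component can own some mass
    candidates = candidates[candidates < float(t.max())]

    def profile(c_values, best, starts, max_iter):
        c_values = np.asarray(c_values, dtype=float)
        if len(c_values) == 0:
            return best
        cs = np.repeat(c_values, starts)
        m = len(cs)
        pi0 = np.empty(m)
        lam0 = np.empty(m)
        pi0[0::starts] = best[0]
        lam0[0::starts] = best[1]
        for s in range(1, starts):
            pi0[s::starts] = rng.uniform(0.05, 0.95, size=len(c_values))
            lam0[s::starts] = lam1 * rng.uniform(0.5, 2.0, size=len(c_values))
        pis, lams, lls = _em_profile(t, cs, pi0, lam0, max_iter=max_iter)
        k = int(np.argmax(lls))
        if lls[k] > best[2]:
            best = (float(pis[k]), float(lams[k]), float(lls[k]), float(cs[k]))
        return best

    coarse = []

    def profile_tracking(c_values, best):
        c_values = np.asarray(c_values, dtype=float)
        cs = np.repeat(c_values, n_starts)
        m = len(cs)
        pi0 = np.empty(m)
        lam0 = np.empty(m)
        pi0[0::n_starts] = best[0]
        lam0[0::n_starts] = best[1]
        for s in range(1, n_starts):
            pi0[s::n_starts] = rng.uniform(0.05, 0.95, size=len(c_values))
            lam0[s::n_starts] = lam1 * rng.uniform(0.5, 2.0, size=len(c_values))
        pis, lams, lls = _em_profile(t, cs, pi0, lam0, max_iter=250)
        for idx in range(m):
            coarse.append((float(lls[idx]), float(cs[idx])))
        k = int(np.argmax(lls))
        if lls[k] > best[2]:
            best = (float(pis[k]), float(lams[k]), float(lls[k]), float(cs[k]))
        return best

    best = profile_tracking(candidates, (0.5, lam1, logl1, 0.0))
    # the profile over C is piecewise smooth with kinks at the observed
    # lengths and can be multimodal: refine on (and just below) the data
    # values around each of the top coarse candidates
    coarse.sort(reverse=True)
    top_cs = []
    for _, c in coarse:
        if all(abs(c - c0) > 1e-12 for c0 in top_cs):
            top_cs.append(c)
        if len(top_cs) == 3:
            break
    eps = 1e-9 * max(1.0, float(t.max()))
    for c_star in top_cs:
        order = int(np.searchsorted(candidates, c_star))
        lo = candidates[max(order - 2, 0)]
        hi = candidates[min(order + 2, len(candidates) - 1)]
        fine = np.unique(t[(t >= lo) & (t <= hi) & (t < float(t.max()))])
        if len(fine) > n_refine:
            fine = fine[np.linspace(0, len(fine) - 1, n_refine).astype(int)]
        if len(fine):
            best = profile(np.concatenate([fine, np.maximum(fine - eps, 0.0)]),
                           best, 2, 250)
    # polish the winner to full convergence
    pi_f, lam_f, ll_f = _em_fixed_c(t, best[3], best[0], best[1], tol=1e-10, max_iter=2000)
    if ll_f > best[2]:
        best = (pi_f, lam_f, ll_f, best[3])
    pi, lam2, logl2, c = best
    if logl2 < logl1 - 1e-6:  # C=0 candidate makes this unreachable
        pi, lam2, logl2, c = 1.0, lam1, logl1, 0.0
    bic2 = -2.0 * logl2 + 3.0 * math.log(n)
    return QuiblFit(lengths.triplet, lengths.sister_pair, n,
                    lambda1=lam1, logl1=logl1, bic1=bic1,
                    pi=pi, lambda2=lam2, c=c, logl2=logl2, bic2=bic2,
                    dbic=bic2 - bic1, low_power=low_power)


def grid_search_fit(lengths: np.ndarray, n_pi: int = 41, n_lam: int = 41,
                    n_c: int = 41) -> tuple[float, float, float, float]:
    """Dense-grid maximizer of the mixture log-likelihood (independent oracle).

    Returns (pi, lambda, C, logL).  Intentionally brute force; used to check
    the EM fit, not to replace it.
    """
    t = np.asarray(lengths, dtype=float)
    lam_hat = len(t) / t.sum()
    pis = np.linspace(0.02, 0.98, n_pi)
    lams = lam_hat * np.geomspace(0.25, 4.0, n_lam)
    cs = np.concatenate([[0.0], np.quantile(t, np.linspace(0.02, 0.98, n_c - 1))])
    best = (-math.inf, None)
    for c in cs:
        for lam in lams:
            for pi in pis:
                ll = mixture_loglik(t, float(pi), float(lam), float(c))
                if ll > best[0]:
                    best = (ll, (float(pi), float(lam), float(c)))
    ll, (pi, lam, c) = best
    return pi, lam, c, ll


# ---------------------------------------------------------------------------
# Scans and pair summaries
# ---------------------------------------------------------------------------

def quibl_scan(trees, ingroup, outgroup: str, species_tree: Tree | None = None,
               seed: int = 0) -> list[QuiblFit]:
    """One fit per (triplet, topology class): C(k,3) x 3 rows.

    Introgression calls are restricted to classes discordant with the species
    tree.  Classes with no usable lengths are reported with n=0 and NaN fits.
    """
    ingroup = sorted(ingroup)
    if len(ingroup) < 3:
        raise QuiblError("need at least 3 ingroup taxa")
    fits = []
    for idx, trio in enumerate(itertools.combinations(ingroup, 3)):
        concordant_pair = None
        if species_tree is not None:
            from .dstat import order_triplet
            p1, p2, _ = order_triplet(trio, species_tree)
            concordant_pair = frozenset((p1, p2))
        classes = triplet_branch_lengths(trees, trio, outgroup)
        for pair in sorted(classes, key=lambda p: tuple(sorted(p))):
            tl = classes[pair]
            discordant = None if concordant_pair is None else pair != concordant_pair
            try:
                fit = fit_quibl_models(tl, seed=seed + idx)
            except QuiblError:
                fit = QuiblFit(tl.triplet, pair, tl.n,
                               lambda1=math.nan, logl1=math.nan, bic1=math.nan,
                               pi=math.nan, lambda2=math.nan, c=math.nan,
                               logl2=math.nan, bic2=math.nan, dbic=math.nan,
                               low_power=True)
            fit.discordant = discordant
            fits.append(fit)
    return fits


def scan_to_frame(fits: list[QuiblFit]) -> pd.DataFrame:
    rows = []
    for f in fits:
        rows.append({
            "triplet": ",".join(f.triplet),
            "topology": "|".join(sorted(f.sister_pair)),
            "N": f.n,
            "lambda1": f.lambda1, "logL1": f.logl1, "BIC1": f.bic1,
            "pi": f.pi, "lambda2": f.lambda2, "C": f.c,
            "logL2": f.logl2, "BIC2": f.bic2, "dBIC": f.dbic,
            "discordant": f.discordant,
            "call": "introgression" if f.introgression_call else "ILS",
        })
    return pd.DataFrame(rows)


def pairwise_introgression(fits: list[QuiblFit], trees=None,
                           taxa=None) -> pd.DataFrame:
    """Mean introgressed-tree proportion per species pair.

    Per discordant class: (1 - pi) x (class count) / (total triplet trees);
    non-significant rows contribute 0.  Averaged over the triplets uniting
    each pair as the class's sister pair.
    """
    if taxa is None:
        taxa = sorted({t for f in fits for t in f.triplet})
    totals: dict[tuple, int] = {}
    for f in fits:
        totals[f.triplet] = totals.get(f.triplet, 0) + f.n
    acc: dict[frozenset, list] = {}
    for f in fits:
        if f.discordant is not True:
            continue
        total = totals[f.triplet]
        if total == 0:
            continue
        value = 0.0
        if f.introgression_call and math.isfinite(f.pi):
            value = (1.0 - f.pi) * f.n / total
        acc.setdefault(f.sister_pair, []).append(value)
    out = pd.DataFrame(0.0, index=taxa, columns=taxa)
    for pair, vals in acc.items():
        a, b = sorted(pair)
        out.loc[a, b] = out.loc[b, a] = float(np.mean(vals))
    return out
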