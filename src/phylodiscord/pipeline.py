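"""End-to-end orchestration: simulate -> spectrum -> concordance -> D ->
branch-length mixture -> clocks -> tree space, with deterministic seeding,
TSV reports and a plain-text log."""

from __future__ import annotations

import dataclasses
import hashlib
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clockrates, concordance, dstat, msc_sim, quibl, topo_spectrum, treekit, treespace
from .msc_sim import Alignment, GeneTreeSet, Scenario, SitePatterns

ALL_STAGES = ("simulate", "spectrum", "concord", "dstat", "quibl", "clock", "treespace")


class PipelineError(Exception):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {message}")


@dataclass
class RunConfig:
    """Resolved run configuration; every threshold is explicit and persisted."""
    scenario: Scenario | None = None
    gene_trees_path: str | None = None
    alignment_path: str | None = None
    loci_table_path: str | None = None
    species_tree_path: str | None = None
    outgroup: str | None = None
    z_threshold: float = 3.0
    dbic_cutoff: float = -10.0
    support_cutoff: float = 80.0
    collapse_below: float = 50.0
    alpha: float = 0.05
    scf_quartets: int = 100
    clock_sites: int = 20000
    treespace_sample: int = 100
    stages: tuple = ALL_STAGES
    seed: int = 0
    outdir: str = "phylodiscord_out"

    def to_dict(self) -> dict:
        d = {k: v for k, v in dataclasses.asdict(self).items() if k != "scenario"}
        d["stages"] = list(self.stages)
        if self.scenario is not None:
            d["scenario"] = msc_sim.scenario_to_dict(self.scenario)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        scenario = d.pop("scenario", None)
        if scenario is not None:
            scenario = msc_sim.scenario_from_dict(scenario)
        known = {f.name for f in dataclasses.fields(cls)}
        kwargs = {k: v for k, v in d.items() if k in known}
        if "stages" in kwargs:
            kwargs["stages"] = tuple(kwargs["stages"])
        return cls(scenario=scenario, **kwargs)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Report writing
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path, index: bool = False, digits: int = 6) -> None:
    """Stable TSV output: UTF-8, header row, NA for missing, 6 significant digits."""
    df.to_csv(path, sep="\t", index=index, na_rep="NA",
              float_format=f"%.{digits}g")


def _file_hash(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        h.update(fh.read())
    return h.hexdigest()[:12]


class _Log:
    def __init__(self, path):
        self.path = Path(path)
        self.path.write_text("")

    def line(self, stage: str, message: str) -> None:
        stamp = time.strftime("%Y-%m-%dT%H:%M:%S")
        with open(self.path, "a") as fh:
            fh.write(f"{stamp}\t{stage}\t{message}\n")


# ---------------------------------------------------------------------------
# Stage implementations
# ---------------------------------------------------------------------------

def _stage_simulate(cfg: RunConfig, outdir: Path, rng_seed: int):
    sc = cfg.scenario
    if sc is None:
        raise PipelineError("simulate", "no scenario in config")
    gts = msc_sim.simulate_gene_trees(sc)
    scaled = msc_sim.scale_branch_lengths(gts, sc)
    aln_streams = np.random.SeedSequence(rng_seed).spawn(len(scaled.trees))
    alignments = [msc_sim.simulate_alignment(t, sc.length, model=sc.model,
                                             seed=np.random.default_rng(s), kappa=sc.kappa)
                  for t, s in zip(scaled.trees, aln_streams)]
    treekit.write_newick_file(gts.trees, outdir / "gene_trees_coal.nwk")
    treekit.write_newick_file(scaled.trees, outdir / "gene_trees_subs.nwk")
    concat = Alignment.concat(alignments)
    concat.to_fasta(outdir / "alignment_concat.fasta")
    bounds = []
    pos = 0
    for i, aln in enumerate(alignments):
        bounds.append({"locus": i + 1, "start": pos, "end": pos + aln.n_sites})
        pos += aln.n_sites
    write_table(pd.DataFrame(bounds), outdir / "loci.tsv")
    msc_sim.save_scenario(sc, outdir / "scenario.yaml")
    return gts, scaled, alignments


def _load_gene_trees(cfg: RunConfig) -> list:
    if cfg.gene_trees_path is None:
        raise PipelineError("input", "no gene trees available (simulate stage off?)")
    return treekit.read_newick_file(cfg.gene_trees_path)


def _pattern_blocks(alignments: list[Alignment], outgroup: str) -> list[SitePatterns]:
    import warnings
    blocks = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for aln in alignments:
            blocks.append(msc_sim.extract_site_patterns(aln, outgroup))
    return blocks


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the configured stages; returns a dict of output paths.

    On stage failure, earlier outputs are kept and :class:`PipelineError`
    names the failing stage.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log = _Log(outdir / "run.log")
    cfg.save(outdir / "config_resolved.yaml")
    log.line("config", f"seed={cfg.seed} stages={','.join(cfg.stages)}")
    stage_seeds = {s: int(np.random.SeedSequence(cfg.seed).entropy) + i
                   for i, s in enumerate(ALL_STAGES)}

    outputs: dict[str, str] = {}
    gts = scaled = None
    alignments: list[Alignment] | None = None
    outgroup = cfg.outgroup or (cfg.scenario.outgroup if cfg.scenario else None)

    def done(stage, *paths):
        for p in paths:
            outputs[Path(p).name] = str(p)
            log.line(stage, f"{Path(p).name} sha256:{_file_hash(p)}")

    try:
        if "simulate" in cfg.stages and cfg.scenario is not None:
            gts, scaled, alignments = _stage_simulate(cfg, outdir, stage_seeds["simulate"])
            done("simulate", outdir / "gene_trees_coal.nwk", outdir / "gene_trees_subs.nwk",
                 outdir / "alignment_concat.fasta", outdir / "loci.tsv")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("simulate", str(exc)) from exc

    gene_trees = scaled.trees if scaled is not None else None
    if gene_trees is None and cfg.gene_trees_path:
        gene_trees = _load_gene_trees(cfg)
    if alignments is None and cfg.alignment_path:
        concat = Alignment.from_fasta(cfg.alignment_path)
        if cfg.loci_table_path:
            loci = pd.read_csv(cfg.loci_table_path, sep="\t")
            alignments = [Alignment(concat.taxa, concat.matrix[:, r.start:r.end])
                          for r in loci.itertuples()]
        else:
            alignments = [concat]

    species_tree = None
    if cfg.species_tree_path:
        species_tree = treekit.read_newick_file(cfg.species_tree_path)[0]

    def _species_tree():
        nonlocal species_tree
        if species_tree is None:
            best, _, _ = concordance.exhaustive_species_tree(gene_trees, outgroup)
            species_tree = treekit.parse_newick(f"({best},{outgroup});")
            treekit.write_newick_file([species_tree], outdir / "species_tree.nwk")
        return species_tree

    for stage in cfg.stages:
        if stage == "simulate":
            continue
        try:
            if stage == "spectrum":
                spec = topo_spectrum.topology_spectrum(gene_trees, outgroup)
                write_table(spec.to_frame(), outdir / "topology_spectrum.tsv")
                done(stage, outdir / "topology_spectrum.tsv")
            elif stage == "concord":
                aln = Alignment.concat(alignments) if alignments else None
                table = concordance.branch_concordance_table(
                    _species_tree(), gene_trees, alignment=aln,
                    n_quartets=cfg.scf_quartets, seed=stage_seeds["concord"],
                    support_cutoff=cfg.support_cutoff)
                write_table(table, outdir / "branch_concordance.tsv")
                done(stage, outdir / "branch_concordance.tsv")
            elif stage == "dstat":
                if not alignments:
                    raise ValueError("no alignments for site patterns")
                blocks = _pattern_blocks(alignments, outgroup)
                ingroup = sorted(set(blocks[0].taxa) - {outgroup})
                results = dstat.triplet_scan(blocks, ingroup, outgroup,
                                             species_tree=_species_tree())
                write_table(dstat.results_to_frame(results), outdir / "dstat.tsv")
                display, raw = dstat.pairwise_mean_abs_d(results, taxa=ingroup)
                write_table(display, outdir / "dstat_pairs.tsv", index=True)
                write_table(raw, outdir / "dstat_pairs_raw.tsv", index=True)
                done(stage, outdir / "dstat.tsv", outdir / "dstat_pairs.tsv",
                     outdir / "dstat_pairs_raw.tsv")
            elif stage == "quibl":
                ingroup = sorted(set(gene_trees[0].leaf_labels()) - {outgroup})
                fits = quibl.quibl_scan(gene_trees, ingroup, outgroup,
                                        species_tree=_species_tree(),
                                        seed=stage_seeds["quibl"])
                write_table(quibl.scan_to_frame(fits), outdir / "quibl.tsv")
                write_table(quibl.pairwise_introgression(fits), outdir / "quibl_pairs.tsv",
                            index=True)
                done(stage, outdir / "quibl.tsv", outdir / "quibl_pairs.tsv")
            elif stage == "clock":
                if cfg.scenario is None:
                    raise ValueError("clock stage needs a scenario (rate truth + tree)")
                sc = cfg.scenario
                times = msc_sim.node_times(sc.species_tree)
                root_t = times[id(sc.species_tree.root)]
                norm_times = {k: v / root_t for k, v in times.items()}
                truth = clockrates.ClockModel(
                    sc.species_tree, norm_times, mu=sc.mu * root_t,
                    multipliers={s.tips: s.r for s in sc.rates}, model=sc.model)
                aln = msc_sim.simulate_alignment(
                    truth.expected_tree(), cfg.clock_sites, model=sc.model,
                    seed=np.random.default_rng(stage_seeds["clock"]))
                clades = [set(s.tips) for s in sc.rates] or [set()]
                clades = [c for c in clades if c]
                fits = clockrates.fit_local_clocks(aln, sc.species_tree, clades,
                                                   model=sc.model, seed=stage_seeds["clock"],
                                                   alpha=cfg.alpha)
                write_table(clockrates.ladder_to_frame(fits), outdir / "clock_ladder.tsv")
                summary = clockrates.clade_rate_summary(
                    truth.expected_tree(), {s.name or ",".join(sorted(s.tips)): set(s.tips)
                                            for s in sc.rates})
                write_table(summary, outdir / "clade_rates.tsv")
                done(stage, outdir / "clock_ladder.tsv", outdir / "clade_rates.tsv")
            elif stage == "treespace":
                sample = gene_trees[: cfg.treespace_sample]
                labels = [f"g{i + 1}" for i in range(len(sample))]
                dmat = treespace.rf_matrix(sample, normalized=True, labels=labels)
                emb = treespace.pcoa(dmat)
                write_table(dmat, outdir / "rf_matrix.tsv", index=True)
                write_table(emb.coordinates, outdir / "pcoa_coords.tsv", index=True)
                done(stage, outdir / "rf_matrix.tsv", outdir / "pcoa_coords.tsv")
        except PipelineError:
            raise
        except Exception as exc:
            log.line(stage, f"FAILED: {exc}")
            raise PipelineError(stage, str(exc)) from exc
    log.line("done", f"{len(outputs)} outputs")
    return outputs
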