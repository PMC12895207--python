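"""End-to-end orchestration: read -> impute -> graft -> profiles -> SES ->
group tests -> dimensionality, with per-stage logging and a JSON manifest.

One global seed deterministically derives every stage seed (blake2b hash
of ``"<global>:<stage>"``), so any stage can be reproduced in isolation
and identical configs yield byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .core import ValidationError, genus_of, impute_traits
from .dimensionality import dimensionality_by_category
from .diversity import diversity_profile
from .groupcomp import group_tests_table
from .io import read_community, read_design, read_traits, read_tree
from .nullmodels import ses_cwm, ses_functional, ses_phylogenetic, summarize_ses
from .phylo import graft_missing_species

logger = logging.getLogger("grassdiv")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed in [0, 2^31)."""
    digest = hashlib.blake2b(f"{global_seed}:{stage}".encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2**31)


@dataclass
class RunConfig:
    """Configuration of one pipeline run (defaults match the study design:
    1000 grafted topologies, 999 randomizations/bootstraps)."""

    community: str
    traits: str
    tree: str
    design: str
    outdir: str = "grassdiv_out"
    n_topologies: int = 1000
    n_rand: int = 999
    n_boot: int = 999
    distance: str = "gower"              # gower | euclidean_log | euclidean_z
    simpson_variant: str = "gini"        # gini | inverse
    iv_variant: str = "r2"               # r2 | abs_r
    adjust: str = "holm"                 # holm | bh | none
    divergence_convention: str = "half_patristic"
    log_transform_traits: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_topologies", "n_rand", "n_boot"):
            if getattr(self, name) < 0 or (name == "n_topologies" and self.n_topologies < 1):
                raise ValidationError(f"{name} must be positive")


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis chain; writes tidy CSVs plus a manifest.

    Returns a dict of the in-memory results keyed by output name.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    timings: dict[str, float] = {}

    def stage(name):
        logger.info("stage %s ...", name)
        timings[name] = time.perf_counter()
        return name

    def done(name, msg=""):
        timings[name] = time.perf_counter() - timings[name]
        logger.info("stage %s done in %.2fs %s", name, timings[name], msg)

    s = stage("read")
    comm = read_community(config.community)
    traits = read_traits(config.traits, log_transform=config.log_transform_traits)
    tree = read_tree(config.tree)
    design = read_design(config.design)
    design.check_covers(comm)
    done(s, f"({len(comm.plot_ids)} plots, {len(comm.species_ids)} species)")

    s = stage("impute")
    if traits.n_missing:
        traits = impute_traits(traits)
    done(s, f"({traits.n_missing} missing after imputation)")

    s = stage("graft")
    in_tree = set(tree.tip_labels)
    missing = [sp for sp in comm.species_ids if sp not in in_tree]
    grafted = graft_missing_species(
        tree, missing, n_topologies=config.n_topologies,
        seed=stage_seed(config.seed, "graft"),
    )
    done(s, f"({len(grafted.grafted_species)} grafted, {len(grafted.dropped_species)} dropped, "
            f"{len(grafted)} topologies)")

    s = stage("profiles")
    profile = diversity_profile(
        comm, traits, grafted, design,
        simpson_variant=config.simpson_variant,
        functional_metric=config.distance,
        convention=config.divergence_convention,
    )
    profile.table.to_csv(outdir / "diversity_profile.csv", index=False)
    cwm_cols = ["plot", "category"] + [c for c in profile.table.columns if c.startswith("CWM_")]
    profile.table[cwm_cols].to_csv(outdir / "cwm.csv", index=False)
    results["profile"] = profile
    done(s)

    s = stage("ses")
    ses_frames = [
        ses_phylogenetic(comm, grafted, n_rand=config.n_rand,
                         seed=stage_seed(config.seed, "ses_phylo"),
                         convention=config.divergence_convention),
        ses_functional(comm, traits, n_rand=config.n_rand,
                       seed=stage_seed(config.seed, "ses_func"),
                       functional_metric=config.distance),
        ses_cwm(comm, traits, n_rand=config.n_rand,
                seed=stage_seed(config.seed, "ses_cwm")),
    ]
    ses = pd.concat(ses_frames, ignore_index=True)
    ses.to_csv(outdir / "ses.csv", index=False)
    ses_summary = summarize_ses(ses, design)
    ses_summary.to_csv(outdir / "ses_summary.csv", index=False)
    results["ses"], results["ses_summary"] = ses, ses_summary
    done(s)

    s = stage("group_tests")
    responses = ["D", "raoD", "raoQ"] + [c for c in profile.table.columns if c.startswith("CWM_")]
    tests, letters = group_tests_table(profile.table, responses, adjust=config.adjust)
    tests.to_csv(outdir / "group_tests.csv", index=False)
    letters.to_csv(outdir / "letters.csv", index=False)
    results["group_tests"], results["letters"] = tests, letters
    done(s)

    s = stage("dimensionality")
    dim = dimensionality_by_category(
        profile, n_boot=config.n_boot,
        seed=stage_seed(config.seed, "dimensionality"),
        iv_variant=config.iv_variant,
    )
    dim.to_csv(outdir / "dimensionality.csv", index=False)
    results["dimensionality"] = dim
    done(s)

    manifest = {
        "software": "grassdiv",
        "version": __version__,
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "stage_seeds": {st: stage_seed(config.seed, st)
                        for st in ("graft", "ses_phylo", "ses_func", "ses_cwm", "dimensionality")},
        "n_plots": len(comm.plot_ids),
        "n_species": len(comm.species_ids),
        "grafted_species": grafted.grafted_species,
        "dropped_species": grafted.dropped_species,
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "outputs": ["diversity_profile.csv", "cwm.csv", "ses.csv", "ses_summary.csv",
                    "group_tests.csv", "letters.csv", "dimensionality.csv"],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    results["manifest"] = manifest
    return results
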