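"""One-command pipeline: build → filter → ladder → analyze → report.

All randomness flows from a single root seed: stage seeds are drawn from a
``numpy.random.SeedSequence`` spawned off the root and recorded in the run
manifest, so a rerun with the same manifest reproduces every report
byte-for-byte (timestamps excluded by design: none are written).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import report as rpt
from .backbone import BackboneConfig, backbone_comparison, lspar_backbone
from .degreefit import rank_fits, degree_sequence
from .descriptives import decompose, density, giant_component, network_summary
from .graphs import build_lemma_lexicon, build_network, inflection_filter
from .lexicon import Lexicon, write_adjlist
from .robustness import robustness_profile
from .sampling import size_ladder
from .smallworld import small_world_analysis

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger("phononet")


@dataclass
class RunConfig:
    """Options for a full pipeline run."""

    sizes: list[int] = field(default_factory=list)
    seed: int = 1
    representation: str = "wordform"  # or "lemma"
    apply_inflection_filter: bool = False
    er_reps: int = 10
    robustness_reps: int = 10
    backbone_s: float = 0.5
    stages: tuple[str, ...] = ("stats", "smallworld", "degreefit", "robustness", "backbone")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, context: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed on {context}: {cause}")
        self.stage = stage
        self.context = context


def _stage_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def run_pipeline(lexicon: Lexicon, config: RunConfig, out_dir: str | Path) -> dict:
    """Execute the full analysis pipeline and write a report bundle.

    Writes one adjacency list per network plus Table-shaped TSV reports
    (components, summary, small-world, degree fits, robustness, backbone)
    and a ``manifest.json`` recording sizes, seeds and configuration. Any
    stage failure aborts with the stage name and network label attached.
    Returns the manifest dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(config.seed)
    seeds = {
        name: _stage_seed(child)
        for name, child in zip(
            ("sampling", "smallworld", "robustness", "backbone"), root.spawn(4)
        )
    }
    manifest = {
        "seed": config.seed,
        "stage_seeds": seeds,
        "representation": config.representation,
        "inflection_filter": config.apply_inflection_filter,
        "sizes": list(config.sizes),
        "backbone_s": config.backbone_s,
        "er_reps": config.er_reps,
        "robustness_reps": config.robustness_reps,
        "networks": {},
    }

    t0 = time.time()
    if config.representation == "lemma":
        lexicon, borrowed = build_lemma_lexicon(lexicon)
        manifest["lemma_transcriptions_borrowed"] = len(borrowed)
    elif config.representation != "wordform":
        raise ValueError(f"unknown representation {config.representation!r}")

    sizes = config.sizes or [len(lexicon)]
    try:
        ladder = size_ladder(lexicon, sorted(sizes), seed=seeds["sampling"])
    except Exception as exc:
        raise PipelineError("sampling", f"sizes {sizes}", exc) from exc
    logger.info("sampling: %d networks in %.1fs", len(ladder), time.time() - t0)

    comp_rows, summary_rows, sw_rows, fit_rows, rb_rows = [], [], [], [], []
    for lex in ladder:
        label = str(len(lex))
        t_net = time.time()
        try:
            g = build_network(lex)
            if config.apply_inflection_filter:
                g, rm = inflection_filter(g)
                manifest["networks"].setdefault(label, {})["inflection_edges_removed"] = rm.n_removed
        except Exception as exc:
            raise PipelineError("build", label, exc) from exc
        write_adjlist(g, out / f"network_{label}.adjlist")
        info = manifest["networks"].setdefault(label, {})
        info["nodes"] = g.number_of_nodes()
        info["edges"] = g.number_of_edges()

        if "stats" in config.stages:
            try:
                s = network_summary(g)
                e_gc = giant_component(g).number_of_edges() if s.components.giant_nodes else 0
                comp_rows.append(
                    rpt.components_row(label, s.n, s.e, s.components, s.density)
                )
                summary_rows.append(rpt.summary_row(label, s, e_gc=e_gc))
            except Exception as exc:
                raise PipelineError("stats", label, exc) from exc
        if "smallworld" in config.stages:
            try:
                sw = small_world_analysis(g, reps=config.er_reps, seed=seeds["smallworld"])
                sw_rows.append(rpt.smallworld_row(label, sw))
                info["small_worldness"] = sw.s
            except Exception as exc:
                raise PipelineError("smallworld", label, exc) from exc
        if "degreefit" in config.stages:
            try:
                fits, errors = rank_fits(degree_sequence(g))
                fit_rows.extend(rpt.fits_rows(label, fits))
                info["best_fit_family"] = fits[0].family
                if errors:
                    info["fit_errors"] = {k: str(v) for k, v in errors.items()}
            except ValueError as exc:
                # degenerate or too-small degree sample: note it, keep going
                info["degreefit_skipped"] = str(exc)
            except Exception as exc:
                raise PipelineError("degreefit", label, exc) from exc
        if "robustness" in config.stages:
            try:
                prof = robustness_profile(
                    giant_component(g),
                    reps=config.robustness_reps,
                    seed=seeds["robustness"],
                )
                for f, a, b in zip(prof.attack.fractions, prof.attack.gc_proportion,
                                   prof.failure.gc_proportion):
                    rb_rows.append([label, f"{f:.2f}", f"{a:.4f}", f"{b:.4f}"])
                info["robustness_divergence_fraction"] = prof.divergence_fraction
            except Exception as exc:
                raise PipelineError("robustness", label, exc) from exc
        if "backbone" in config.stages:
            try:
                bb = lspar_backbone(g, BackboneConfig(s=config.backbone_s,
                                                      community_seed=seeds["backbone"]))
                write_adjlist(bb, out / f"backbone_{label}.adjlist")
                cmp_report = backbone_comparison(g, bb, seed=seeds["backbone"])
                rpt.write_tsv(
                    out / f"backbone_report_{label}.tsv",
                    ["measure", "original", "backbone"],
                    rpt.backbone_rows(cmp_report),
                )
                info["backbone_edges"] = bb.number_of_edges()
            except Exception as exc:
                raise PipelineError("backbone", label, exc) from exc
        logger.info("network %s analyzed in %.1fs", label, time.time() - t_net)

    if comp_rows:
        rpt.write_tsv(out / "components.tsv", ["size"] + rpt.COMPONENT_COLUMNS, comp_rows)
        rpt.write_tsv(out / "summary.tsv", ["size"] + rpt.SUMMARY_COLUMNS, summary_rows)
    if sw_rows:
        rpt.write_tsv(out / "smallworld.tsv", ["size"] + rpt.SMALLWORLD_COLUMNS, sw_rows)
    if fit_rows:
        rpt.write_tsv(out / "degree_fits.tsv", ["size"] + rpt.FIT_COLUMNS, fit_rows)
    if rb_rows:
        rpt.write_tsv(out / "robustness.tsv",
                      ["size", "fraction", "attack", "failure"], rb_rows)
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("pipeline complete in %.1fs", time.time() - t0)
    return manifest
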