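"""End-to-end pipeline: trials -> connectivity -> networks -> metrics -> stats.

``run_pipeline`` composes the source-level stages on an HDF5 trial
container (typically produced by ``simulate_study``): trials are trimmed
to their central 10 s, band-averaged LPS matrices are computed per trial
(intra-brain for SOLO, hyperbrain for PAIRED), thresholded at median+MAD,
reduced to graph and asymmetry metrics with surrogate normalization,
aggregated to session means, and fed to the mixed-design statistics.
Failures are reported per trial and the pipeline continues over the
remaining trials.
"""

from __future__ import annotations

import json
import logging
from collections import defaultdict
from dataclasses import asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import asymmetry as asym
from . import graphmetrics as gm
from .connectivity import lps_matrix_for_trial
from .io import (
    PipelineConfig,
    write_adjacency_csv,
    write_adjacency_graphml,
    write_lps_csv,
    write_table,
    write_trials_hdf5,
    read_trials,
)
from .networks import binarize, extract_blocks, mad_threshold
from .simulate import (
    GroundTruthGraph,
    SimulationConfig,
    generate_dyad_trial,
    matched_pairs_truth,
)
from .stats import (
    STUDY_SESSIONS,
    SessionDesign,
    aggregate_session_means,
    design_frame,
    hyperbrain_group_ttests,
    mixed_anova,
)
from .trials import default_atlas, trim_trial, validate_trial

logger = logging.getLogger(__name__)


def _default_truth(n_per_brain: int, rng: np.random.Generator) -> GroundTruthGraph:
    """A modest seeded truth: a few intra- and inter-brain lagged couplings."""
    n = 2 * n_per_brain
    perm = rng.permutation(n)
    pairs = [(int(perm[2 * k]), int(perm[2 * k + 1])) for k in range(n // 6)]
    return matched_pairs_truth(pairs)


def simulate_study(
    out_path: str | Path,
    config: PipelineConfig | None = None,
    designs: list[SessionDesign] | None = None,
    n_trials_per_condition: int = 3,
    sim_kwargs: dict | None = None,
) -> list:
    """Generate a synthetic study (all sessions, SOLO and PAIRED) to HDF5.

    Each session receives its own sub-seed; SOLO trials reuse the dyad
    generator with an independent truth and keep one brain per juggler.
    Returns the list of written trials.
    """
    config = config if config is not None else PipelineConfig()
    designs = list(designs) if designs is not None else list(STUDY_SESSIONS)
    sim_kwargs = dict(sim_kwargs or {})
    trials = []
    for s_i, design in enumerate(designs):
        rng = np.random.default_rng(
            np.random.SeedSequence([int(config.seed), 100 + s_i])
        )
        sim = SimulationConfig(
            n_trials=n_trials_per_condition,
            seed=int(rng.integers(0, 2**31 - 1)),
            **sim_kwargs,
        )
        truth = _default_truth(sim.n_rois_per_brain, rng)
        for k in range(n_trials_per_condition):
            t1, t2 = generate_dyad_trial(sim, truth, k)
            for t in (t1, t2):
                t.session_id = design.session_id
                t.condition = "PAIRED"
            trials += [t1, t2]
        solo_sim = replace(sim, seed=int(rng.integers(0, 2**31 - 1)))
        solo_truth = _default_truth(sim.n_rois_per_brain, rng)
        for k in range(n_trials_per_condition):
            t1, t2 = generate_dyad_trial(solo_sim, solo_truth, k)
            for t in (t1, t2):
                t.session_id = design.session_id
                t.condition = "SOLO"
            trials += [t1, t2]
    write_trials_hdf5(out_path, trials, config)
    return trials


INTRA_MEASURES = ("G", "C", "SWI", "D", "Lat_intra", "RA_intra")


def _intra_metric_rows(
    adj, atlas, session, condition, juggler, trial_index, config, rng
):
    m = gm.compute_network_metrics(
        adj,
        n_surrogates=config.n_surrogates,
        seed=rng,
        convention=config.convention,
        swap_factor=config.swap_factor,
    )
    lat = asym.lateralization_intra(adj, atlas)
    ra = asym.regional_asymmetry_intra(adj, atlas)
    values = dict(m.as_dict(), Lat_intra=lat.value, RA_intra=ra.value)
    return [
        {
            "session": session,
            "condition": condition,
            "unit": juggler,
            "trial": trial_index,
            "measure": k,
            "value": v,
        }
        for k, v in values.items()
    ]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage on the trials in ``config.input_path``.

    Writes per-trial LPS and adjacency matrices, the tidy metrics table,
    session means and statistics under ``config.output_path``; returns the
    in-memory results dictionary.
    """
    if config.input_path is None or config.output_path is None:
        raise ValueError("config must set input_path and output_path")
    out = Path(config.output_path)
    (out / "lps").mkdir(parents=True, exist_ok=True)
    (out / "networks").mkdir(exist_ok=True)
    config.to_file(out / "config.yaml")

    region_classes = asym.load_region_classes(config.region_class_path)
    trials = read_trials(
        config.input_path,
        atlas_factory=lambda b: default_atlas(b, region_classes),
    )
    logger.info("read %d trials", len(trials))

    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 999]))
    rows: list[dict] = []
    failures: list[str] = []

    by_key = defaultdict(dict)
    solo = []
    for t in trials:
        if t.condition == "PAIRED":
            by_key[(t.session_id, t.trial_index)][t.juggler_id] = t
        else:
            solo.append(t)

    def process(trial_like, session, condition, trial_index):
        if isinstance(trial_like, tuple):
            lps = lps_matrix_for_trial(
                trial_like,
                band=config.band,
                window=config.window,
                step=config.step,
                calibrate=config.calibrate,
            )
            tag = f"{session}_{condition}_trial{trial_index}_hyper"
        else:
            lps = lps_matrix_for_trial(
                trial_like,
                band=config.band,
                window=config.window,
                step=config.step,
                calibrate=config.calibrate,
            )
            tag = f"{session}_{condition}_{trial_like.juggler_id}_trial{trial_index}"
        write_lps_csv(lps, out / "lps" / f"{tag}.csv", config)
        return lps, tag

    # optional pooled thresholding: one median+MAD per (session, condition,
    # matrix kind) over all trials' value sets instead of per trial
    pooled_thresholds: dict[tuple, float] = {}
    if config.threshold_mode == "pooled":
        pool: dict[tuple, list[np.ndarray]] = defaultdict(list)
        for t in solo:
            try:
                tt = validate_trial(trim_trial(t, config.trim_duration))
                lps = lps_matrix_for_trial(
                    tt, band=config.band, window=config.window,
                    step=config.step, calibrate=config.calibrate,
                )
                pool[(t.session_id, "SOLO", t.juggler_id)].append(lps.pair_values())
            except Exception:  # noqa: BLE001 - failures reported in main pass
                pass
        for (session, k), pair in sorted(by_key.items()):
            if set(pair) != {"J1", "J2"}:
                continue
            try:
                t1 = validate_trial(trim_trial(pair["J1"], config.trim_duration))
                t2 = validate_trial(trim_trial(pair["J2"], config.trim_duration))
                lps = lps_matrix_for_trial(
                    (t1, t2), band=config.band, window=config.window,
                    step=config.step, calibrate=config.calibrate,
                )
                pool[(session, "PAIRED", "hyper")].append(lps.pair_values())
            except Exception:  # noqa: BLE001
                pass
        pooled_thresholds = {
            key: mad_threshold(np.concatenate(vals)) for key, vals in pool.items()
        }

    def threshold_for(session, condition, kind):
        return pooled_thresholds.get((session, condition, kind))

    # SOLO trials: one intra-brain network per juggler per trial
    for t in solo:
        try:
            t = validate_trial(trim_trial(t, config.trim_duration))
            lps, tag = process(t, t.session_id, "SOLO", t.trial_index)
            adj = binarize(lps, threshold_for(t.session_id, "SOLO", t.juggler_id))
            write_adjacency_csv(adj, out / "networks" / f"{tag}.csv", config)
            rows += _intra_metric_rows(
                adj, t.atlas, t.session_id, "SOLO", t.juggler_id,
                t.trial_index, config, rng,
            )
        except Exception as exc:  # noqa: BLE001 - keep processing other trials
            failures.append(f"SOLO {t.session_id}/{t.juggler_id}/{t.trial_index}: {exc}")
            logger.error(failures[-1])

    # PAIRED trials: hyperbrain network + intra blocks + inter indices
    for (session, k), pair in sorted(by_key.items()):
        if set(pair) != {"J1", "J2"}:
            failures.append(f"PAIRED {session}/trial{k}: missing a juggler")
            continue
        try:
            t1 = validate_trial(trim_trial(pair["J1"], config.trim_duration))
            t2 = validate_trial(trim_trial(pair["J2"], config.trim_duration))
            lps, tag = process((t1, t2), session, "PAIRED", k)
            adj = binarize(lps, threshold_for(session, "PAIRED", "hyper"))
            write_adjacency_csv(adj, out / "networks" / f"{tag}.csv", config)
            write_adjacency_graphml(adj, out / "networks" / f"{tag}.graphml")
            hyper = gm.compute_network_metrics(
                adj,
                n_surrogates=config.n_surrogates,
                seed=rng,
                convention=config.convention,
                swap_factor=config.swap_factor,
            )
            rows += [
                {
                    "session": session,
                    "condition": "PAIRED",
                    "unit": "hyperbrain",
                    "trial": k,
                    "measure": meas,
                    "value": val,
                }
                for meas, val in hyper.as_dict().items()
            ]
            intra1, intra2, _ = extract_blocks(adj)
            dyad = asym.ROIAtlas(t1.atlas.rois + t2.atlas.rois)
            for jug, block, atlas in (
                ("J1", intra1, t1.atlas),
                ("J2", intra2, t2.atlas),
            ):
                rows += _intra_metric_rows(
                    block, atlas, session, "PAIRED", jug, k, config, rng
                )
                lat = asym.lateralization_inter(adj, dyad, jug)
                ra = asym.regional_asymmetry_inter(adj, dyad, jug)
                rows += [
                    {
                        "session": session,
                        "condition": "PAIRED",
                        "unit": jug,
                        "trial": k,
                        "measure": meas,
                        "value": val,
                    }
                    for meas, val in (
                        ("Lat_inter", lat.value),
                        ("RA_inter", ra.value),
                    )
                ]
        except Exception as exc:  # noqa: BLE001
            failures.append(f"PAIRED {session}/trial{k}: {exc}")
            logger.error(failures[-1])

    trial_metrics = pd.DataFrame(rows)
    write_table(trial_metrics, out / "trial_metrics.csv", config)
    results: dict = {"n_trials": len(trials), "failures": failures}
    if trial_metrics.empty:
        (out / "results.json").write_text(json.dumps(results, indent=2))
        return results

    session_means = aggregate_session_means(trial_metrics)
    design = design_frame()
    session_means = session_means.merge(design, on="session", how="left")
    write_table(session_means, out / "session_metrics.csv", config)

    # intra-brain mixed ANOVAs: condition (SOLO/PAIRED) x skill (J1/J2)
    # within sessions, matched/unmatched between sessions
    intra = session_means[session_means["unit"].isin(["J1", "J2"])].rename(
        columns={"unit": "skill"}
    )
    anova_rows = []
    for dv in INTRA_MEASURES:
        sub = intra[intra["measure"] == dv]
        try:
            for res in mixed_anova(
                sub, dv, within=["condition", "skill"], between="matched"
            ):
                anova_rows.append(dict(asdict(res), dv=dv, analysis="three-factor"))
            for grp, frame in sub.groupby("matched"):
                if frame["session"].nunique() < 2:
                    continue
                label = "matched" if grp else "unmatched"
                for res in mixed_anova(frame, dv, within=["condition", "skill"]):
                    anova_rows.append(
                        dict(asdict(res), dv=dv, analysis=f"two-factor-{label}")
                    )
        except ValueError as exc:
            logger.warning("ANOVA for %s skipped: %s", dv, exc)
    # inter-brain indices: skill within x matched between (PAIRED only)
    inter = session_means[
        session_means["measure"].isin(["Lat_inter", "RA_inter"])
    ].rename(columns={"unit": "skill"})
    for dv in ("Lat_inter", "RA_inter"):
        sub = inter[inter["measure"] == dv]
        try:
            for res in mixed_anova(sub, dv, within=["skill"], between="matched"):
                anova_rows.append(dict(asdict(res), dv=dv, analysis="inter-brain"))
        except ValueError as exc:
            logger.warning("ANOVA for %s skipped: %s", dv, exc)
    anova_table = pd.DataFrame(anova_rows)
    write_table(anova_table, out / "anova_results.csv", config)

    hyper_rows = session_means[session_means["unit"] == "hyperbrain"]
    ttest_rows = []
    try:
        for res in hyperbrain_group_ttests(hyper_rows):
            ttest_rows.append(asdict(res))
    except ValueError as exc:
        logger.warning("hyperbrain t-tests skipped: %s", exc)
    ttable = pd.DataFrame(ttest_rows)
    write_table(ttable, out / "hyperbrain_ttests.csv", config)

    results.update(
        {
            "trial_metrics": trial_metrics,
            "session_metrics": session_means,
            "anova": anova_table,
            "hyperbrain_ttests": ttable,
        }
    )
    summary = {
        "n_trials": len(trials),
        "n_failures": len(failures),
        "n_metric_rows": len(trial_metrics),
        "config_hash": config.config_hash,
        "seed": config.seed,
    }
    (out / "results.json").write_text(json.dumps(summary, indent=2))
    return results
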