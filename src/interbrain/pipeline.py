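"""End-to-end synthetic experiment: simulate -> feedback -> spectra -> stats.

Stage functions (``simulate_cohort``, ``online_summaries``,
``coupling_spectra``, ``generate_scores``, ``stats_chain``) are composable
pieces; ``run_experiment`` chains them into the full study emulation:
a cohort of real-feedback and sham-feedback dyads, closed-loop feedback
replay in the matching mode, offline task-related coupling spectra,
questionnaire scores from the serial path model conditioned on each dyad's
realized band coupling, and the full statistical chain. Everything is
reproducible from the config's root seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import stats
from .io import RunConfig, write_scores_csv
from .offline import (CouplingSpectrum, band_average, dyad_spectrum,
                      spectra_to_frame, task_related)
from .online import run_feedback_session, summarize_trace
from .scores import PathModel, simulate_scores
from .simulate import DyadSimConfig, DyadRecording, simulate_dyad
from .timeline import make_timeline

log = logging.getLogger("interbrain")


def _dyad_config(config: RunConfig, kappa: float, seed_seq) -> DyadSimConfig:
    # Fold the SeedSequence entropy into one 31-bit value for DyadSimConfig.
    seed = int(seed_seq.generate_state(1, np.uint32)[0]) & 0x7FFFFFFF
    return DyadSimConfig(coupling_strength=kappa,
                         target_band=config.target_band, seed=seed)


def experiment_timeline(config: RunConfig):
    return make_timeline(n_rounds=config.n_rounds, round_s=config.round_s,
                         break_s=config.break_s, rest_s=config.rest_s)


def simulate_cohort(config: RunConfig,
                    timeline=None) -> list[tuple[DyadRecording, str]]:
    """Simulate both arms; returns (recording, feedback mode) pairs."""
    if timeline is None:
        timeline = experiment_timeline(config)
    dyads = []
    for arm, kappa, mode in (("real", config.kappa_real, "real"),
                             ("sham", config.kappa_sham, "sham")):
        for i in range(config.n_per_arm):
            cfg = _dyad_config(config, kappa,
                               config.substream_seed("sim", len(dyads)))
            rec = simulate_dyad(cfg, timeline,
                                dyad_id=f"{arm}_{i:03d}", group=arm)
            dyads.append((rec, mode))
    return dyads


def online_summaries(dyads, config: RunConfig) -> pd.DataFrame:
    """Mean online coherence per dyad, feedback replayed in each arm's mode."""
    rows = []
    for k, (rec, mode) in enumerate(dyads):
        trace = run_feedback_session(
            rec, mode=mode, window_s=config.window_s,
            update_rate_hz=config.rate_hz, norm_max=config.norm_max,
            sham_seed=config.substream_seed("sham", k).entropy)
        rows.append({"dyad_id": rec.dyad_id, "group": rec.group,
                     "mean_online_coherence": summarize_trace(trace)})
        log.info("online %s: %.4f", rec.dyad_id,
                 rows[-1]["mean_online_coherence"])
    return pd.DataFrame(rows)


def coupling_spectra(dyads, config: RunConfig
                     ) -> tuple[list[CouplingSpectrum], pd.DataFrame]:
    """Task-related coupling spectra and band averages for every dyad."""
    freqs = config.freqs()
    spectra, rows = [], []
    for rec, _ in dyads:
        task = dyad_spectrum(rec, "task", freqs=freqs,
                             window_s=config.window_s,
                             discard_tail_s=config.discard_tail_s,
                             n_cycles=config.n_cycles)
        rest = dyad_spectrum(rec, "rest", freqs=freqs,
                             window_s=config.window_s,
                             n_cycles=config.n_cycles)
        tr = task_related(task, rest)
        spectra.append(tr)
        rows.append({"dyad_id": rec.dyad_id, "group": rec.group,
                     "band_coupling": band_average(tr, config.target_band)})
        log.info("spectrum %s: band=%.4f", rec.dyad_id,
                 rows[-1]["band_coupling"])
    return spectra, pd.DataFrame(rows)


def generate_scores(band_df: pd.DataFrame, config: RunConfig,
                    path_model: PathModel | None = None) -> pd.DataFrame:
    """Questionnaire scores conditioned on realized band coupling."""
    if path_model is None:
        path_model = PathModel.study_like()
    coupling = band_df["band_coupling"].to_numpy()
    x = (coupling - coupling.mean()) / coupling.std(ddof=1)
    rng = np.random.default_rng(config.substream_seed("scores"))
    model = dataclasses.replace(path_model, n_dyads=len(x))
    scores = simulate_scores(model, coupling=x,
                             groups=band_df["group"].to_numpy(),
                             likert=config.likert,
                             delta_intercepts=config.delta_intercepts,
                             rng=rng)
    scores["dyad_id"] = band_df["dyad_id"].to_numpy()
    # store the raw band coupling (the generator saw its z-score)
    scores["coupling_band"] = coupling
    return scores


def stats_chain(online_df: pd.DataFrame, spectra: list[CouplingSpectrum],
                scores: pd.DataFrame, config: RunConfig) -> dict:
    """Full statistical chain on one cohort's outputs."""
    freqs = config.freqs()
    groups = scores["group"].to_numpy()
    is_real = groups == "real"
    res: dict = {"config_hash": config.hash(), "seed": config.seed}

    onl = online_df["mean_online_coherence"].to_numpy()
    res["online"] = dataclasses.asdict(
        stats.t_test_auto(onl[is_real], onl[~is_real],
                          gate_p=config.levene_gate))

    tests = stats.freqwise_tests(
        [s for s, r in zip(spectra, is_real) if r],
        [s for s, r in zip(spectra, is_real) if not r],
        gate_p=config.levene_gate)
    pvals = [t.p for t in tests]
    reject, p_adj = stats.bh_fdr(pvals, q=config.fdr_q)
    res["freqwise"] = {"freqs": freqs.tolist(),
                       "t": [t.t for t in tests], "p": pvals,
                       "p_fdr": p_adj.tolist(),
                       "significant_freqs": freqs[reject].tolist()}

    coupling = scores["coupling_band"].to_numpy()
    res["band"] = dataclasses.asdict(
        stats.t_test_auto(coupling[is_real], coupling[~is_real],
                          gate_p=config.levene_gate))

    for outcome in ("sc", "si", "ps"):
        an = stats.mixed_anova_2x2(scores, outcome)
        res[f"anova_{outcome}"] = {
            k: dataclasses.asdict(v) for k, v in an.effects.items()}
        res[f"simple_effects_{outcome}"] = {
            k: dataclasses.asdict(v)
            for k, v in stats.simple_effects(scores, outcome).items()}

    jc = scores["joint_control"].to_numpy()
    res["joint_control"] = dataclasses.asdict(
        stats.t_test_auto(jc[is_real], jc[~is_real],
                          gate_p=config.levene_gate))

    d_si = scores["si_post"] - scores["si_pre"]
    d_ps = scores["ps_post"] - scores["ps_pre"]
    d_sc = scores["sc_post"] - scores["sc_pre"]
    res["correlations"] = {
        "coupling_joint_control": stats.pearson(coupling, jc),
        "joint_control_d_si": stats.pearson(jc, d_si),
        "joint_control_d_ps": stats.pearson(jc, d_ps),
        "joint_control_d_sc": stats.pearson(jc, d_sc),
        "d_si_d_sc": stats.pearson(d_si, d_sc),
        "d_ps_d_sc": stats.pearson(d_ps, d_sc),
    }

    if len(coupling) >= 10:
        med = stats.serial_mediation(
            coupling, jc, d_si, d_ps, d_sc, n_boot=config.n_boot,
            seed=int(config.substream_seed("bootstrap")
                     .generate_state(1, np.uint32)[0]) & 0x7FFFFFFF)
        res["mediation"] = {"paths": med.paths,
                            "indirect": med.indirect.to_dict(orient="records"),
                            "n": med.n, "n_boot": med.n_boot}
    else:
        log.warning("too few dyads for mediation; skipped")
        res["mediation"] = None
    return res


def run_experiment(config: RunConfig, out_dir=None,
                   path_model: PathModel | None = None) -> dict:
    """Run the full synthetic experiment; returns the result bundle.

    With ``out_dir`` set, writes scores.csv, spectra.csv, online.csv,
    results.json and config.yaml; tables carry the config hash and seed.
    """
    log.info("simulating %d dyads per arm (seed=%d, hash=%s)",
             config.n_per_arm, config.seed, config.hash())
    dyads = simulate_cohort(config)
    online_df = online_summaries(dyads, config)
    spectra, band_df = coupling_spectra(dyads, config)
    scores = generate_scores(band_df, config, path_model)
    res = stats_chain(online_df, spectra, scores, config)

    bundle = {"results": res, "scores": scores, "online": online_df,
              "spectra": spectra_to_frame(spectra), "band": band_df}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        stamp = {"config_hash": config.hash(), "seed": config.seed}
        write_scores_csv(out / "scores.csv", scores)
        online_df.assign(**stamp).to_csv(out / "online.csv", index=False)
        bundle["spectra"].assign(**stamp).to_csv(out / "spectra.csv",
                                                 index=False)
        (out / "results.json").write_text(json.dumps(res, indent=2))
        config.to_yaml(out / "config.yaml")
    return bundle
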