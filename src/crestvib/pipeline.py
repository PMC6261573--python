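"""End-to-end orchestration: fixture generation and the multi-stage analysis run.

``generate_fixtures`` writes a synthetic study to disk — a population of
crests with known resonance parameters, sweep/impulse/playback/wing-shaking
trials and bending curves — and ``run_pipeline`` replays the full analysis
(track or load series -> sweep fits -> ring-downs -> forced-response spectra
-> statistics) writing CSV/JSON results plus a provenance-stamped run log.
"""

from __future__ import annotations

import sys
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .errors import CrestVibError, FitFailureError
from .forced import band_power_ratio, dominant_peak, power_spectrum
from .impulse import consistency_check, fit_ringdown
from .stats import adjusted_repeatability, fit_bending_trial, fit_variance_model, summarize_crests
from .sweep import fit_lorentzian, sweep_spectra
from .synthetic import (
    DEFAULT_SEED,
    VIDEO_FS,
    OscillatorParams,
    make_chirp,
    make_forcing,
    simulate_response,
)

#: Group-level ground-truth means used for the synthetic population
#: (out-of-plane orientation; in-plane sits lower by ORIENTATION_SHIFT_HZ).
GROUP_TRUTH = {
    "male": dict(f_r=26.3, Q=6.2),
    "female": dict(f_r=28.1, Q=4.8),
}
#: Out-of-plane resonant frequencies run ~2.4 Hz above in-plane.
ORIENTATION_SHIFT_HZ = 2.4
#: Among-crest and within-crest (trial) spreads of f_r (Hz) and Q.
SD_FR_CREST = 1.0
SD_FR_TRIAL = 0.25
SD_Q_CREST = 0.5
#: Rattle repetition rates of the three playback stimuli (Hz).
PLAYBACK_RATES = (26.7, 25.3, 24.6)
#: Wing-shaking drive frequency (Hz).
WINGSHAKE_HZ = 4.95


@dataclass
class PipelineConfig:
    """Configuration of a full analysis run over a fixture-style input tree."""

    in_dir: str
    out_dir: str
    seed: int = DEFAULT_SEED
    fs: float = VIDEO_FS
    sweep: dict = field(default_factory=dict)       # sweep_spectra/fit options
    forced: dict = field(default_factory=dict)      # power_spectrum options
    stats: dict = field(default_factory=dict)       # repeatability options
    verbose: bool = False

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


def _log(cfg: PipelineConfig, msg: str) -> None:
    if cfg.verbose:
        print(msg, file=sys.stderr)


def generate_fixtures(
    seed: int = DEFAULT_SEED,
    out_dir: str | Path = "fixtures",
    n_male: int = 7,
    n_female: int = 8,
    n_trials: int = 3,
    orientations: tuple[str, ...] = ("out_of_plane", "in_plane"),
    sweep_f_end: float = 80.0,
    sweep_rate: float = 1.33,
    fs: float = VIDEO_FS,
    noise_sd: float = 0.05,
    playback_duration: float = 120.0,
    n_vortex_crests: int = 3,
) -> dict:
    """Write a synthetic study tree with known ground truth.

    Defaults mirror the study population: 15 crests (7 male near 26.3 Hz,
    8 female near 28.1 Hz out-of-plane), 3 sweep trials each per orientation
    (0-80 Hz at 1.33 Hz/s, 240 Hz sampling, 5% multiplicative trial noise),
    vortex ring-downs, the three playback rattle rates plus a white-noise
    control, a wing-shaking trial, and bending force-displacement curves.
    Returns the ground-truth dictionary (also written as JSON).
    """
    out = Path(out_dir)
    rng = np.random.default_rng(seed)
    truth: dict = dict(seed=seed, crests={}, sweep=dict(
        f_end=sweep_f_end, rate=sweep_rate, fs=fs, noise_sd=noise_sd))

    sexes = ["male"] * n_male + ["female"] * n_female
    meta_rows = []
    (out / "sweeps").mkdir(parents=True, exist_ok=True)
    for i, sex in enumerate(sexes):
        cid = f"crest{i + 1:02d}"
        g = GROUP_TRUTH[sex]
        fr_crest = g["f_r"] + rng.normal(0.0, SD_FR_CREST)
        q_crest = max(g["Q"] + rng.normal(0.0, SD_Q_CREST), 2.0)
        truth["crests"][cid] = dict(sex=sex, f_r=fr_crest, Q=q_crest)
        meta_rows.append(dict(
            crest_id=cid, sex=sex,
            flag_area=rng.normal(6.0 if sex == "male" else 5.0, 0.8),
            length=rng.normal(5.4 if sex == "male" else 5.3, 0.3),
            width=rng.normal(6.1 if sex == "male" else 5.5, 0.5),
            n_feathers=int(rng.integers(25, 32)),
            pct_unaligned=float(np.clip(rng.normal(5, 6), 0, 50)),
            pct_short=float(np.clip(rng.normal(4, 4), 0, 25)),
        ))
        for orient in orientations:
            fr_o = fr_crest - (ORIENTATION_SHIFT_HZ if orient == "in_plane" else 0.0)
            for k in range(n_trials):
                fr_trial = fr_o + rng.normal(0.0, SD_FR_TRIAL)
                params = OscillatorParams(f_r=fr_trial, Q=q_crest, label=cid)
                chirp = make_chirp(0.0, sweep_f_end, sweep_rate, fs=fs)
                trial_seed = int(rng.integers(0, 2**31 - 1))
                trial = simulate_response(params, chirp, mode="transfer",
                                          noise_sd=noise_sd,
                                          noise_kind="multiplicative",
                                          seed=trial_seed)
                stem = f"{cid}_{orient}_t{k + 1}"
                cio.write_series_csv(out / "sweeps" / f"{stem}_drive.csv",
                                     chirp.t, chirp.u)
                cio.write_series_csv(out / "sweeps" / f"{stem}_response.csv",
                                     trial.t, trial.response)
    pd.DataFrame(meta_rows).to_csv(out / "metadata.csv", index=False)

    # vortex impulse trials for a subset of crests (out-of-plane)
    (out / "vortex").mkdir(exist_ok=True)
    for cid in list(truth["crests"])[:n_vortex_crests]:
        c = truth["crests"][cid]
        params = OscillatorParams(f_r=c["f_r"], Q=c["Q"], label=cid)
        imp = make_forcing("impulse", dict(width=0.005, magnitude=50.0, center=0.1),
                           fs=2400.0, duration=3.0)
        trial = simulate_response(params, imp, mode="ode", noise_sd=1e-4,
                                  seed=int(rng.integers(0, 2**31 - 1)))
        cio.write_series_csv(out / "vortex" / f"{cid}.csv", trial.t, trial.response)

    # playback trials: first female crest, three rattle rates + white noise
    (out / "playback").mkdir(exist_ok=True)
    fem = next(c for c in truth["crests"].values() if c["sex"] == "female")
    fem_params = OscillatorParams(f_r=fem["f_r"], Q=fem["Q"])
    rattle_rms = None
    for rate in PLAYBACK_RATES:
        train = make_forcing("impulse_train", dict(rate=rate, magnitude=1.0),
                             fs=2400.0, duration=playback_duration,
                             seed=int(rng.integers(0, 2**31 - 1)))
        rattle_rms = train.rms
        trial = simulate_response(fem_params, train, mode="ode", noise_sd=1e-5,
                                  seed=int(rng.integers(0, 2**31 - 1)))
        stem = f"rattle_{rate:.1f}"
        cio.write_series_csv(out / "playback" / f"{stem}.csv", trial.t, trial.response)
        cio.write_json(out / "playback" / f"{stem}.json",
                       dict(kind="impulse_train", rate=rate))
    wn = make_forcing("white_noise", dict(rms=rattle_rms), fs=2400.0,
                      duration=playback_duration,
                      seed=int(rng.integers(0, 2**31 - 1)))
    trial = simulate_response(fem_params, wn, mode="ode", noise_sd=1e-5,
                              seed=int(rng.integers(0, 2**31 - 1)))
    cio.write_series_csv(out / "playback" / "white_noise.csv", trial.t, trial.response)
    cio.write_json(out / "playback" / "white_noise.json",
                   dict(kind="white_noise", rate=PLAYBACK_RATES[0]))

    # wing-shaking trial (male params, 4.95 Hz sine)
    (out / "wingshake").mkdir(exist_ok=True)
    male = next(c for c in truth["crests"].values() if c["sex"] == "male")
    sine = make_forcing("sine", dict(frequency=WINGSHAKE_HZ, amplitude=1.0),
                        fs=2400.0, duration=60.0)
    trial = simulate_response(OscillatorParams(f_r=male["f_r"], Q=male["Q"]),
                              sine, mode="ode", noise_sd=1e-5,
                              seed=int(rng.integers(0, 2**31 - 1)))
    cio.write_series_csv(out / "wingshake" / "wingshake.csv", trial.t, trial.response)
    cio.write_json(out / "wingshake" / "wingshake.json",
                   dict(kind="sine", rate=WINGSHAKE_HZ))

    # bending: linear up to ~10 mm then plateauing, k in the measured range
    (out / "bending").mkdir(exist_ok=True)
    rows = []
    for cid in list(truth["crests"])[:6]:
        k_true = rng.uniform(0.0022, 0.0054)
        truth["crests"][cid]["k"] = k_true
        for trial_i in range(1, 4):
            d = np.arange(0.0, 16.0, 0.5)
            F = k_true * np.minimum(d, 10.0)
            F += rng.normal(0.0, 2e-5, size=len(d))
            for di, Fi in zip(d, F):
                rows.append(dict(crest_id=cid, trial=trial_i,
                                 displacement_mm=di, force_n=Fi))
    pd.DataFrame(rows).to_csv(out / "bending" / "bending.csv", index=False)

    cio.write_json(out / "ground_truth.json", truth)
    return truth


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage present in the input tree; return the results bundle.

    Stage outputs: ``sweep_fits.csv``, ``ringdowns.csv``, ``forced_summary.json``,
    ``stats_summary.json``, ``bending_fits.csv`` and ``run_log.json`` in
    ``out_dir``.  Deterministic for a fixed seed; input-file ordering is
    normalized by sorting.
    """
    in_dir = Path(config.in_dir)
    out_dir = Path(config.out_dir)
    if not in_dir.is_dir():
        raise FileNotFoundError(f"input directory {in_dir} does not exist")
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    results: dict = {}

    sweep_dir = in_dir / "sweeps"
    if sweep_dir.is_dir():
        rows = []
        for drv in sorted(sweep_dir.glob("*_drive.csv")):
            stem = drv.name[: -len("_drive.csv")]
            rsp = sweep_dir / f"{stem}_response.csv"
            if not rsp.exists():
                raise FileNotFoundError(f"missing response file for {stem}")
            t, d, fs = cio.read_series_csv(drv)
            _, x, _ = cio.read_series_csv(rsp)
            try:
                tf = sweep_spectra(d, x, fs, **config.sweep)
                fit = fit_lorentzian(tf)
            except CrestVibError as exc:
                raise type(exc)(f"sweep stage failed on {stem}: {exc}") from exc
            parts = stem.split("_t")
            cid_orient = parts[0]
            cid, orient = cid_orient.split("_", 1)
            rows.append(dict(crest_id=cid, orientation=orient,
                             trial=int(parts[1]) if len(parts) > 1 else 1,
                             f_r=fit.f_r, delta_f=fit.delta_f, Q=fit.Q,
                             scale=fit.scale, r2_adj=fit.r2_adj))
            _log(config, f"sweep {stem}: f_r={fit.f_r:.2f} Q={fit.Q:.2f}")
        fits = pd.DataFrame(rows)
        fits.to_csv(out_dir / "sweep_fits.csv", index=False)
        results["sweep_fits"] = fits

    vortex_dir = in_dir / "vortex"
    if vortex_dir.is_dir():
        rows = []
        for path in sorted(vortex_dir.glob("*.csv")):
            t, x, fs = cio.read_series_csv(path)
            ring = fit_ringdown(x, fs)
            rows.append(dict(crest_id=path.stem, f_o=ring.f_o, tau=ring.tau,
                             A0=ring.A0, r2_adj=ring.r2_adj))
        rings = pd.DataFrame(rows)
        if "sweep_fits" in results and not rings.empty:
            # deviation vs the crest's out-of-plane mean sweep fit, in delta_f units
            sf = results["sweep_fits"]
            devs = []
            for _, r in rings.iterrows():
                sub = sf[(sf.crest_id == r.crest_id)
                         & (sf.orientation == "out_of_plane")]
                if len(sub):
                    from .impulse import RingDownFit, predict_fo
                    fr, dfw = sub.f_r.mean(), sub.delta_f.mean()
                    pred = predict_fo(fr, fr / dfw)
                    devs.append(abs(r.f_o - pred) / dfw)
                else:
                    devs.append(np.nan)
            rings["deviation_df_units"] = devs
        rings.to_csv(out_dir / "ringdowns.csv", index=False)
        results["ringdowns"] = rings

    forced_summary = {}
    for stage, band in (("playback", (20.0, 35.0)), ("wingshake", (2.0, 10.0))):
        d = in_dir / stage
        if not d.is_dir():
            continue
        seg = config.forced.get("segment_s", 2.0 if stage == "playback" else 20.0)
        spectra = {}
        for path in sorted(d.glob("*.csv")):
            t, x, fs = cio.read_series_csv(path)
            spec = power_spectrum(x, fs, segment_s=seg)
            meta_path = path.with_suffix(".json")
            meta = cio.read_json(meta_path) if meta_path.exists() else {}
            peak = dominant_peak(spec, band)
            spectra[path.stem] = (spec, meta)
            forced_summary[f"{stage}/{path.stem}"] = dict(
                peak_hz=peak.frequency, peak_power=peak.power,
                stimulus=meta.get("kind"), rate=meta.get("rate"))
        if stage == "playback" and "white_noise" in spectra:
            wn_spec, wn_meta = spectra["white_noise"]
            rate = wn_meta.get("rate", PLAYBACK_RATES[0])
            key = f"rattle_{rate:.1f}"
            if key in spectra:
                ratio = band_power_ratio(wn_spec, spectra[key][0], center=rate)
                forced_summary["control_ratio_white_noise_pct"] = 100.0 * ratio
    if forced_summary:
        cio.write_json(out_dir / "forced_summary.json", forced_summary)
        results["forced"] = forced_summary

    if "sweep_fits" in results and len(results["sweep_fits"]):
        fits = results["sweep_fits"].copy()
        meta_path = in_dir / "metadata.csv"
        if meta_path.exists():
            meta = pd.read_csv(meta_path)
            fits = fits.merge(meta, on="crest_id", how="left")
        else:
            fits["sex"] = "unknown"
        summary = summarize_crests(fits)
        stats_out = {
            "per_crest": summary["per_crest"].to_dict(orient="records"),
            "groups": summary["groups"].to_dict(orient="records"),
        }
        if fits.crest_id.nunique() >= 5:
            vm = fit_variance_model(
                fits, "f_r", fixed=[c for c in ("sex", "orientation")
                                    if fits[c].nunique() > 1],
                heteroskedastic=True)
            rep = adjusted_repeatability(
                vm, n_boot=config.stats.get("n_boot", 200), seed=config.seed)
            stats_out["repeatability_f_r"] = dict(
                value=rep.value, ci_low=rep.ci_low, ci_high=rep.ci_high)
        cio.write_json(out_dir / "stats_summary.json", stats_out)
        results["stats"] = stats_out

    bend_path = in_dir / "bending" / "bending.csv"
    if bend_path.exists():
        bdf = pd.read_csv(bend_path)
        rows = []
        for (cid, trial), grp in bdf.groupby(["crest_id", "trial"], sort=True):
            try:
                bf = fit_bending_trial(grp.displacement_mm.to_numpy(),
                                       grp.force_n.to_numpy())
                rows.append(dict(crest_id=cid, trial=trial, k=bf.k,
                                 linear_range_mm=bf.linear_range_mm,
                                 r2_adj=bf.r2_adj))
            except FitFailureError:
                rows.append(dict(crest_id=cid, trial=trial, k=np.nan,
                                 linear_range_mm=np.nan, r2_adj=np.nan))
        bends = pd.DataFrame(rows)
        bends.to_csv(out_dir / "bending_fits.csv", index=False)
        results["bending"] = bends

    log = dict(
        in_dir=str(in_dir), out_dir=str(out_dir), seed=config.seed,
        config_hash=cio.config_hash(asdict(config)),
        stages=sorted(k for k in results),
        elapsed_s=round(time.time() - t0, 3),
    )
    cio.write_json(out_dir / "run_log.json", log)
    results["run_log"] = log
    return results
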