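"""End-to-end orchestration: simulate -> preprocess -> spectral -> waveform
-> decode -> distinctiveness -> lmm, with tidy CSV outputs and a JSON log.

Every output table carries participant/session keys; one master seed fans
out deterministically to per-session generator seeds, so a rerun with the
same config produces identical outputs.
"""

from __future__ import annotations

import json
import time
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import decoding as dec
from . import devstats, preprocess, spectral, synth, waveform
from .design import ExperimentDesign
from .montage import gsn128

STAGES = ("simulate", "preprocess", "spectral", "waveform", "decode",
          "distinctiveness", "lmm")

DEFAULT_CONFIG = {
    "cohort": "default",            # or an explicit participant list
    "n_sequences": 3,
    "rng_seed": 0,
    "profile": "infant",
    "roi_set": "default",
    "category_cap_hz": 30.0,
    "image_harmonics": 4,
    "noise_bins": 5,
    "spectrum_cap_hz": 20.0,
    "cluster_permutations": 1000,
    "min_epochs_per_condition": 20,
    "decoding_correction": "fdr",
}


def _validate_config(config: dict) -> dict:
    cfg = dict(DEFAULT_CONFIG)
    unknown = set(config) - set(DEFAULT_CONFIG)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg.update(config)
    if cfg["roi_set"] is None:
        raise ValueError("config field 'roi_set' is required")
    preprocess.get_profile(cfg["profile"])
    if cfg["n_sequences"] < 1:
        raise ValueError("n_sequences must be >= 1")
    return cfg


def run_pipeline(config: dict, out_dir, stages=STAGES) -> Path:
    """Run the pipeline through the named stages, writing CSVs to out_dir."""
    cfg = _validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    design = ExperimentDesign()
    montage = gsn128()
    roi_set = spectral.load_roi_set(cfg["roi_set"])
    profile = preprocess.get_profile(cfg["profile"])
    hset_cat = spectral.classify_bins(design, cfg["category_cap_hz"])
    hset_img = spectral.classify_bins(
        design, cfg["image_harmonics"] * design.image_rate + 1e-9)
    hset_noise = spectral.classify_bins(design, 2 * design.image_rate + 1e-9)
    log = {"config": cfg, "stages": list(stages), "counts": {}}

    cohort_cfg = (synth.default_cohort_config()
                  if cfg["cohort"] == "default" else cfg["cohort"])
    sessions, cohort_table = synth.generate_cohort(
        cohort_cfg, montage=montage, design=design,
        with_recordings=False, base_seed=cfg["rng_seed"])
    cohort_table.to_csv(out / "cohort.csv", index=False)

    if "simulate" not in stages:
        _write_log(log, out, t0)
        return out

    reports, spec_rows, meas_rows, dist_rows, rsm_rows = [], [], [], [], []
    session_data = []  # per kept session: keys, roi mean segments per cond
    for sess in sessions:
        rec = synth.simulate_recording(design, montage, sess.spec,
                                       cfg["n_sequences"])
        keys = {"participant_id": sess.participant_id,
                "session_id": sess.session_id, "age_days": sess.age_days,
                "group_label": synth.age_group(sess.age_days)}
        if "preprocess" not in stages:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            eps, report = preprocess.preprocess_recording(
                rec, montage, design, profile)
        # session-level epoch count criterion, per category
        valid_counts = {
            c: int(np.sum(eps.valid[eps.condition == c].mean(axis=1) > 0.5))
            for c in design.category_names}
        excluded = min(valid_counts.values()) < cfg["min_epochs_per_condition"]
        reports.append({**keys, **{f"n_valid_{k}": v for k, v in valid_counts.items()},
                        "n_repaired": len(report["repaired_channels"]),
                        "rejected_fraction": report["rejected_fraction"],
                        "excluded": excluded})
        if excluded or "spectral" not in stages:
            continue

        roi_segments = {}
        for cond in design.category_names:
            seg, _ = spectral.pair_segments(eps, cond)
            spec_ch = spectral.dft_spectrum(seg, eps.sampling_rate)
            roi_spectra = {}
            for roi in roi_set.names:
                try:
                    roi_spectra[roi] = spectral.roi_participant_spectrum(
                        spec_ch, roi_set[roi], eps.channel_labels)
                except ValueError:
                    continue
            if len(roi_spectra) < len(roi_set.names):
                continue
            roi_segments[cond] = {
                roi: np.nanmean(
                    seg[[eps.channel_labels.index(c) for c in roi_set[roi]]],
                    axis=0)
                for roi in roi_set.names}
            kcap = int(cfg["spectrum_cap_hz"] / spec_ch.resolution)
            for roi, rs in roi_spectra.items():
                amps = rs.amplitude()[:kcap]
                for k, a in enumerate(amps):
                    spec_rows.append({**keys, "roi": roi, "condition": cond,
                                      "bin_hz": (k + 1) * rs.resolution,
                                      "real": rs.coefficients[k].real,
                                      "imag": rs.coefficients[k].imag,
                                      "amplitude": a})
            meas = {**keys, "category": cond}
            for roi in ("LOT", "ROT"):
                if roi in roi_spectra:
                    meas[f"rms_amplitude_{roi}"] = spectral.category_rms_amplitude(
                        roi_spectra[roi], design)
            if "OCC" in roi_spectra:
                meas["noise_amplitude"] = spectral.noise_amplitude(
                    roi_spectra["OCC"], hset_noise, cfg["noise_bins"])
            if "waveform" in stages:
                for roi in ("LOT", "ROT"):
                    wf = waveform.category_reconstruction(
                        roi_segments[cond][roi], design, hset_cat)
                    pk = _signed_peak(wf, eps.sampling_rate,
                                      waveform.CATEGORY_PEAK_WINDOW)
                    meas[f"peak_amplitude_{roi}"] = pk.amplitude
                    meas[f"peak_latency_{roi}"] = pk.latency_ms
                occ_img = waveform.image_reconstruction(
                    roi_segments[cond]["OCC"], design, hset_img)
                cyc = waveform.cycle_average_visual(occ_img, design)
                pk1 = waveform.peak_measure(
                    cyc, eps.sampling_rate, waveform.FIRST_DEFLECTION_WINDOW, -1)
                pk2 = waveform.peak_measure(
                    cyc, eps.sampling_rate,
                    waveform.second_deflection_window(sess.age_days), 1)
                meas["visual_peak1_latency"] = pk1.latency_ms
                meas["visual_peak1_amplitude"] = pk1.amplitude
                meas["visual_peak2_latency"] = pk2.latency_ms
                meas["visual_peak2_amplitude"] = pk2.amplitude
            meas_rows.append(meas)

        if len(roi_segments) == design.n_categories:
            session_data.append((keys, roi_segments))

        if "distinctiveness" in stages:
            halves = dec.split_half_patterns(eps, roi_set, design, hset_cat)
            odd = {c: h["odd"] for c, h in halves.items()}
            even = {c: h["even"] for c, h in halves.items()}
            rsm = dec.compute_rsm(odd, even, design.category_names)
            for ci in design.category_names:
                for cj in design.category_names:
                    rsm_rows.append({**keys, "odd_category": ci,
                                     "even_category": cj,
                                     "correlation": rsm.loc[ci, cj]})
            for cat in design.category_names:
                if cat in halves:
                    rec_d = dec.distinctiveness(rsm, cat)
                    dist_rows.append({**keys, "category": cat,
                                      "within": rec_d.within,
                                      "between_mean": rec_d.between_mean,
                                      "distinctiveness": rec_d.distinctiveness})

    if reports:
        pd.DataFrame(reports).to_csv(out / "preprocess_report.csv", index=False)
        log["counts"]["sessions_kept"] = int(
            (~pd.DataFrame(reports)["excluded"]).sum())
    if spec_rows:
        pd.DataFrame(spec_rows).to_csv(out / "spectra.csv", index=False)
    if meas_rows:
        pd.DataFrame(meas_rows).to_csv(out / "measurements.csv", index=False)
    if rsm_rows:
        pd.DataFrame(rsm_rows).to_csv(out / "rsm.csv", index=False)
    if dist_rows:
        pd.DataFrame(dist_rows).to_csv(out / "distinctiveness.csv", index=False)

    # ---- group-level spectral statistics, waveform clusters and decoding
    if "spectral" in stages and session_data:
        _group_stage(session_data, design, roi_set, hset_cat, hset_img,
                     cfg, out, stages, log)

    # ---- developmental mixed models
    if "lmm" in stages and dist_rows and meas_rows:
        _lmm_stage(pd.DataFrame(dist_rows), pd.DataFrame(meas_rows), out, log)

    _write_log(log, out, t0)
    return out


def _signed_peak(wf, fs, window):
    pos = waveform.peak_measure(wf, fs, window, 1)
    neg = waveform.peak_measure(wf, fs, window, -1)
    return pos if abs(pos.amplitude) >= abs(neg.amplitude) else neg


def _group_stage(session_data, design, roi_set, hset_cat, hset_img, cfg, out,
                 stages, log):
    rows_stats, rows_dec_hits, rows_clusters = [], [], []
    acc_by_group = {}
    groups = sorted({k["group_label"] for k, _ in session_data})
    rng = np.random.default_rng(cfg["rng_seed"] + 1)
    for g in groups:
        members = [(k, s) for k, s in session_data if k["group_label"] == g]
        if len(members) < 3:
            continue
        # Hotelling T2 on ROI-averaged coefficients, vector averaging implied
        bins = {**{f"category_h{i+1}": f
                   for i, f in enumerate(hset_cat.frequencies("category")[:2])},
                **{f"image_h{i+1}": f
                   for i, f in enumerate(hset_img.frequencies("image"))}}
        for cond in design.category_names:
            for roi in roi_set.names:
                segs = [s[cond][roi] for _, s in members]
                spectra = [spectral.dft_spectrum(x, design.sampling_rate_analysis)
                           for x in segs]
                group_spec = spectral.vector_average(spectra)
                pvals, names = [], []
                for name, f in bins.items():
                    k = group_spec.bin_index(round(f / group_spec.resolution)
                                             * group_spec.resolution)
                    coefs = np.array([s.coefficients[k] for s in spectra])
                    res = spectral.tcirc_test(coefs)
                    pvals.append(res.p)
                    names.append((name, f, res, np.abs(group_spec.coefficients[k])))
                fam = [n for n, *_ in names]
                rej = spectral.fdr_bh(pvals, q=0.05)
                for (name, f, res, amp), p_r in zip(names, rej):
                    rows_stats.append({
                        "group_label": g, "condition": cond, "roi": roi,
                        "bin_name": name, "bin_hz": f, "group_amplitude": amp,
                        "t2": res.statistic, "f_value": res.f_value,
                        "p": res.p, "significant_fdr": bool(p_r), "n": res.n})
                if "waveform" in stages and len(members) >= 5:
                    waves = np.stack([
                        waveform.category_reconstruction(x, design, hset_cat)
                        for x in segs])
                    cres = waveform.cluster_permutation_test(
                        waves, n_perm=cfg["cluster_permutations"], rng=rng,
                        sampling_rate=design.sampling_rate_analysis)
                    for (a, b, m), p, sig in zip(cres.clusters, cres.cluster_p,
                                                 cres.significant):
                        rows_clusters.append({
                            "group_label": g, "condition": cond, "roi": roi,
                            "start_ms": a, "end_ms": b, "mass": m,
                            "cluster_p": p, "significant": bool(sig)})
        if "decode" in stages:
            pats, pids = [], []
            for k, s in members:
                pats.append(np.stack([
                    dec.build_group_pattern({
                        roi: waveform.category_reconstruction(
                            s[cond][roi], design, hset_cat)
                        for roi in roi_set.names})
                    for cond in design.category_names]))
                pids.append(f"{k['participant_id']}/{k['session_id']}")
            res = dec.loocv_wta_decode(
                np.stack(pats), categories=list(design.category_names),
                participants=pids)
            h = res.hits.copy()
            h["group_label"] = g
            rows_dec_hits.append(h)
            acc_by_group[g] = res.accuracy.to_numpy()
    if rows_stats:
        pd.DataFrame(rows_stats).to_csv(out / "group_spectral_stats.csv",
                                        index=False)
    if rows_clusters:
        pd.DataFrame(rows_clusters).to_csv(out / "group_clusters.csv",
                                           index=False)
    if rows_dec_hits:
        pd.concat(rows_dec_hits).to_csv(out / "decoding_hits.csv", index=False)
        tests = dec.accuracy_vs_chance(acc_by_group,
                                       correction=cfg["decoding_correction"])
        tests.to_csv(out / "decoding_groups.csv", index=False)
        log["counts"]["decoded_groups"] = len(acc_by_group)


def _lmm_stage(dist, meas, out, log):
    fe_rows = []

    def record(model_name, res):
        for _, r in res.fixed_effects.iterrows():
            fe_rows.append({"model": model_name, **r.to_dict(),
                            "n_obs": res.n_obs,
                            "n_participants": res.n_participants,
                            "random_intercept_var": res.random_intercept_var,
                            "converged": res.converged})

    try:
        record("distinctiveness ~ log_age * category",
               devstats.fit_lmm(dist, "distinctiveness",
                                fixed="log_age * category"))
        post = devstats.posthoc_by_level(dist, "distinctiveness", "category")
        post.to_csv(out / "posthoc_distinctiveness.csv", index=False)
    except ValueError as e:
        log["counts"]["lmm_distinctiveness_skipped"] = str(e)
    for roi in ("LOT", "ROT"):
        col = f"rms_amplitude_{roi}"
        if col in meas:
            sub = meas.dropna(subset=[col])
            try:
                record(f"{col} ~ log_age * category",
                       devstats.fit_lmm(sub, col, fixed="log_age * category"))
            except ValueError as e:
                log["counts"][f"lmm_{col}_skipped"] = str(e)
    if "noise_amplitude" in meas:
        noise = (meas.groupby(["participant_id", "session_id", "age_days"],
                              as_index=False)["noise_amplitude"].mean())
        try:
            record("noise_amplitude ~ log_age", devstats.noise_lmm(noise))
        except ValueError as e:
            log["counts"]["lmm_noise_skipped"] = str(e)
    if fe_rows:
        pd.DataFrame(fe_rows).to_csv(out / "lmm_fixed_effects.csv", index=False)


def _write_log(log, out, t0):
    log["elapsed_s"] = round(time.time() - t0, 2)
    with open(out / "log.json", "w") as f:
        json.dump(log, f, indent=1, default=str)
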