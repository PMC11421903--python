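"""End-to-end orchestration: simulate -> features -> groups -> classify -> similarity.

Each stage reads/writes plain CSV (and WAV for audio); every output file
starts with a provenance comment carrying the config hash and seed, so a
result can always be traced back to the exact run that produced it.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from . import classify, features, similarity, social
from .simulate import Dataset, GroundTruth, SimConfig, generate_dataset

log = logging.getLogger("rumblesig")

__all__ = [
    "config_hash",
    "write_csv",
    "read_csv",
    "write_dataset",
    "load_dataset",
    "run_simulate",
    "run_features",
    "run_groups",
    "run_classify",
    "run_similarity",
    "run_all",
]


def config_hash(config: SimConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.md5(payload).hexdigest()[:12]


def write_csv(df: pd.DataFrame, path: Path, config: SimConfig, seed: int) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# rumblesig config_hash={config_hash(config)} seed={seed}\n")
        df.to_csv(fh, index=False)


def read_csv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


# ---------------------------------------------------------------------------
# dataset <-> disk


def write_dataset(ds: Dataset, outdir: Path, write_wav: bool = True) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg, seed = ds.config, ds.config.seed
    if write_wav:
        wav_dir = outdir / "wav"
        wav_dir.mkdir(exist_ok=True)
        for call_id, wav in ds.waveforms.items():
            peak = np.max(np.abs(wav))
            pcm = np.int16(np.clip(wav / peak if peak > 0 else wav, -1, 1) * 32767)
            wavfile.write(wav_dir / f"{call_id}.wav", cfg.sample_rate_hz, pcm)
    calls = ds.calls.copy()
    if write_wav:
        calls["wav_path"] = calls["call_id"].map(lambda c: f"wav/{c}.wav")
    write_csv(calls.drop(columns=["f1_mean_hz"]), outdir / "calls.csv", cfg, seed)
    write_csv(ds.truth.callers, outdir / "callers.csv", cfg, seed)
    write_csv(ds.calls[["call_id", "f1_mean_hz"]], outdir / "truth.csv", cfg, seed)
    s = ds.sightings.copy()
    s["ids"] = s["ids"].map(";".join)
    write_csv(s, outdir / "sightings.csv", cfg, seed)
    write_csv(ds.relatedness, outdir / "relatedness.csv", cfg, seed)
    with open(outdir / "config.json", "w") as fh:
        json.dump(cfg.to_dict(), fh, indent=2)


def load_dataset(outdir: Path) -> Dataset:
    outdir = Path(outdir)
    with open(outdir / "config.json") as fh:
        d = json.load(fh)
    d["callers_per_population"] = tuple(d["callers_per_population"])
    d["contexts"] = tuple(d["contexts"])
    cfg = SimConfig(**d)
    calls = read_csv(outdir / "calls.csv")
    truth_df = read_csv(outdir / "truth.csv")
    calls = calls.merge(truth_df, on="call_id", how="left")
    callers = read_csv(outdir / "callers.csv")
    matriarchs = {}
    for core, grp in callers.groupby("core_group"):
        top = grp[grp["age_years"] == grp["age_years"].max()]
        matriarchs[core] = min(top["caller_id"])
    waveforms = {}
    for call_id, rel in zip(calls["call_id"], calls.get("wav_path", [])):
        rate, pcm = wavfile.read(outdir / rel)
        waveforms[call_id] = pcm.astype(float) / 32767.0
    s = read_csv(outdir / "sightings.csv")
    s["ids"] = s["ids"].map(lambda v: tuple(v.split(";")))
    rel = read_csv(outdir / "relatedness.csv")
    return Dataset(
        config=cfg,
        calls=calls.drop(columns=["wav_path"], errors="ignore"),
        waveforms=waveforms,
        truth=GroundTruth(callers=callers, matriarchs=matriarchs),
        sightings=s,
        relatedness=rel,
    )


# ---------------------------------------------------------------------------
# stages (in-memory; the CLI wires them to disk)


def _annotate_groups(calls: pd.DataFrame, callers: pd.DataFrame) -> pd.DataFrame:
    cols = ["caller_id", "bond_group", "core_group", "age_years"]
    return calls.merge(callers[cols], on="caller_id", how="left")


def run_simulate(config: SimConfig, outdir: Path | None = None,
                 write_wav: bool = True) -> Dataset:
    t0 = time.time()
    ds = generate_dataset(config)
    log.info(
        "simulate: %d callers, %d calls, %d sighting rows (seed=%d, %.1fs)",
        len(ds.truth.callers), len(ds.calls), len(ds.sightings),
        config.seed, time.time() - t0,
    )
    if outdir is not None:
        write_dataset(ds, outdir, write_wav=write_wav)
    return ds


def run_features(ds: Dataset, outdir: Path | None = None) -> pd.DataFrame:
    t0 = time.time()
    stft = features.StftParams(sample_rate_hz=ds.config.sample_rate_hz)
    table = features.extract_features_table(ds.waveforms, stft)
    log.info("features: %d calls x %d columns (%.1fs)",
             len(table), table.shape[1] - 1, time.time() - t0)
    if outdir is not None:
        write_csv(table, Path(outdir) / "features.csv", ds.config, ds.config.seed)
    return table


def run_groups(ds: Dataset, outdir: Path | None = None,
               min_sightings: int = 20) -> social.SocialPartition:
    t0 = time.time()
    ages = dict(zip(ds.truth.callers["caller_id"], ds.truth.callers["age_years"]))
    part = social.infer_tiers(ds.sightings, ages, min_sightings=min_sightings)
    frame = part.to_frame()
    log.info("groups: %d individuals -> %d cores, %d bonds (%.1fs)",
             len(frame), frame["core_group"].nunique(),
             frame["bond_group"].nunique(), time.time() - t0)
    if outdir is not None:
        write_csv(frame, Path(outdir) / "partition.csv", ds.config, ds.config.seed)
        a = social.association_matrix(ds.sightings, min_sightings=min_sightings)
        adf = pd.DataFrame(a.matrix, index=a.ids, columns=a.ids).reset_index(
            names="individual"
        )
        write_csv(adf, Path(outdir) / "association.csv", ds.config, ds.config.seed)
    return part


def run_classify(
    ds: Dataset,
    feature_table: pd.DataFrame,
    levels: tuple[str, ...] = classify.LEVELS,
    n_iter: int = 150,
    seed: int = 0,
    outdir: Path | None = None,
    spec: classify.ForestSpec | None = None,
) -> dict[str, classify.ExperimentResult]:
    calls = _annotate_groups(ds.calls, ds.truth.callers)
    # the bond/core experiments use one population only (association data
    # exist for a single population in the emulated design)
    main_pop = calls["population"].mode().iloc[0]
    mel_cols = features.mel_feature_names()
    results: dict[str, classify.ExperimentResult] = {}
    for level in levels:
        t0 = time.time()
        data = calls if level in ("population", "individual") else calls[
            calls["population"] == main_pop
        ].reset_index(drop=True)
        res = classify.run_experiment(
            feature_table, data, level,
            spec=spec, n_iter=n_iter, seed=seed, feature_cols=mel_cols,
        )
        results[level] = res
        log.info(
            "classify[%s]: median acc %.3f vs baseline %.3f, median p %.3g (%.1fs)",
            level, res.median_accuracy, res.median_baseline, res.median_p,
            time.time() - t0,
        )
        if level == "population":
            res_f1 = classify.run_experiment(
                feature_table, data, level,
                spec=spec, n_iter=n_iter, seed=seed + 1,
                feature_cols=list(features.CONTOUR_STAT_NAMES),
            )
            results["population_f1"] = res_f1
    if outdir is not None:
        summary_rows = []
        for name, res in results.items():
            write_csv(res.iterations, Path(outdir) / f"experiment_{name}.csv",
                      ds.config, seed)
            summary_rows.append(
                {
                    "level": name,
                    "n_calls": res.n_calls,
                    "n_classes": res.n_classes,
                    "median_accuracy": res.median_accuracy,
                    "median_baseline": res.median_baseline,
                    "median_p": res.median_p,
                    "test_fraction_mean": res.test_fraction_mean,
                    "test_fraction_sd": res.test_fraction_sd,
                }
            )
        write_csv(pd.DataFrame(summary_rows), Path(outdir) / "experiment_summary.csv",
                  ds.config, seed)
    return results


def run_similarity(
    ds: Dataset,
    feature_table: pd.DataFrame,
    seed: int = 0,
    n_trees: int = 8000,
    outdir: Path | None = None,
) -> dict[str, object]:
    calls = _annotate_groups(ds.calls, ds.truth.callers)
    mel_cols = features.mel_feature_names()
    feat = feature_table.set_index("call_id")
    ages = dict(zip(ds.truth.callers["caller_id"], ds.truth.callers["age_years"]))
    out: dict[str, object] = {}

    def _prox(data: pd.DataFrame, label_col: str, s: int) -> np.ndarray:
        X = feat.loc[data["call_id"], mel_cols].to_numpy()
        forest = similarity.proximity_forest(
            X, data[label_col].to_numpy(), seed=s, n_trees=n_trees
        )
        return similarity.proximity_matrix(forest, X)

    t0 = time.time()
    # population model (binary pair class)
    P = _prox(calls, "population", seed)
    pop_pairs = similarity.build_pair_table(calls, P, scheme="population", ages=ages)
    out["population_pairs"] = pop_pairs
    out["population_fit"] = similarity.fit_pairclass_glmm(pop_pairs, "population")
    log.info("similarity[population]: %d pairs (%.1fs)", len(pop_pairs), time.time() - t0)

    # three-state models within the main population
    main_pop = calls["population"].mode().iloc[0]
    for level, scheme in (("core", "core3"), ("bond", "core3")):
        t0 = time.time()
        data = classify.eligible_calls(
            calls[calls["population"] == main_pop].reset_index(drop=True), level
        )
        label = "core_group" if level == "core" else "bond_group"
        if data[label].nunique() < 2:
            log.warning("similarity[%s]: <2 classes, skipped", level)
            continue
        P = _prox(data, label, seed + (17 if level == "core" else 29))
        pairs = similarity.build_pair_table(data, P, scheme=scheme, ages=ages,
                                            relatedness=ds.relatedness)
        fit = similarity.fit_pairclass_glmm(pairs, scheme)
        out[f"{level}_pairs"] = pairs
        out[f"{level}_fit"] = fit
        out[f"{level}_contrasts"] = similarity.pairwise_contrasts(fit)
        # social vs genetic model with binary pair class
        bpairs = similarity.build_pair_table(
            data, P, scheme=f"{level}_binary", ages=ages, relatedness=ds.relatedness
        )
        out[f"{level}_relatedness_fit"] = similarity.fit_relatedness_glmm(
            bpairs, f"{level}_binary"
        )
        log.info("similarity[%s]: %d pairs (%.1fs)", level, len(pairs), time.time() - t0)

    if outdir is not None:
        outdir = Path(outdir)
        for key, val in out.items():
            if key.endswith("_pairs"):
                write_csv(val, outdir / f"pairs_{key[:-6]}.csv", ds.config, seed)
            elif key.endswith("_contrasts"):
                write_csv(val, outdir / f"contrasts_{key[:-10]}.csv", ds.config, seed)
            elif key.endswith("_fit"):
                fit = val
                tbl = pd.DataFrame(
                    {"term": fit.coef.index, "coefficient": fit.coef.to_numpy(),
                     "se": fit.se.to_numpy()}
                )
                tbl = pd.concat(
                    [tbl, fit.deviance_table.rename(columns={"term": "term"})],
                    axis=0, ignore_index=True,
                )
                write_csv(tbl, outdir / f"glmm_{key[:-4]}.csv", ds.config, seed)
    return out


def run_all(
    config: SimConfig,
    outdir: Path,
    n_iter: int = 150,
    levels: tuple[str, ...] = classify.LEVELS,
    n_prox_trees: int = 8000,
    force: bool = False,
    write_wav: bool = True,
) -> dict:
    """Full pipeline on one synthetic dataset; returns a summary dict.

    Refuses to overwrite an existing output directory unless ``force``.
    """
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise FileExistsError(
            f"output directory {outdir} is not empty (use force to overwrite)"
        )
    ds = run_simulate(config, outdir, write_wav=write_wav)
    feat = run_features(ds, outdir)
    part = run_groups(ds, outdir, min_sightings=min(20, max(1, config.n_days // 3)))
    results = run_classify(ds, feat, levels=levels, n_iter=n_iter,
                           seed=config.seed, outdir=outdir)
    sim = run_similarity(ds, feat, seed=config.seed, n_trees=n_prox_trees,
                         outdir=outdir)
    summary = {
        "n_calls": len(ds.calls),
        "n_callers": len(ds.truth.callers),
        "levels": {
            name: {
                "median_accuracy": res.median_accuracy,
                "median_baseline": res.median_baseline,
                "median_p": res.median_p,
            }
            for name, res in results.items()
        },
        "inferred_cores": part.to_frame()["core_group"].nunique(),
        "inferred_bonds": part.to_frame()["bond_group"].nunique(),
    }
    if "core_contrasts" in sim:
        summary["core_contrasts"] = sim["core_contrasts"].to_dict("records")
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    return summary
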