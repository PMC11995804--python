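"""End-to-end orchestration of the analysis stages.

Stages (each reads the previous stage's files from the output directory):

1. ``simulate`` -- synthetic cohort: cohort table CSV, signals HDF5, layout JSON
2. ``features`` -- per-subject spectral tensors HDF5
3. ``manova``   -- frequency-wise Riemannian distance MANOVA tables (CSV)
4. ``cluster``  -- TFCE cluster test results (CSV + JSON)
5. ``model``    -- Table-4-style logistic model comparison (CSV) + AME tables
6. ``classify`` -- stacked classifier AUC summary (CSV + JSON)
7. ``cpi``      -- conditional permutation importance table (CSV)

A single global seed is fanned out to named substreams per stage.  Re-running
skips stages whose outputs exist, unless forced; a JSON manifest records the
configuration hash, per-stage outputs and wall times.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cluster as cl
from . import cohort as ch
from . import importance as imp
from . import risk
from . import spd
from . import stacking as st
from . import wavelets as wv

STAGES = ("simulate", "features", "manova", "cluster", "model", "classify",
          "cpi")


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    outdir: str = "megprog_run"
    stages: tuple = STAGES
    seed: int = 0
    cohort: dict = field(default_factory=dict)      # CohortSpec overrides
    wavelet: dict = field(default_factory=lambda: {
        "f_min": 1.0, "f_max": 64.0, "bandwidth_oct": 0.35,
        "sampling_oct": 0.05})
    stats: dict = field(default_factory=lambda: {
        "n_perm": 1000, "e": 0.5, "h": 2.0, "alpha": 0.05, "rank": 65,
        "dwpli_rank": 5, "metrics": ["cov"]})
    model: dict = field(default_factory=lambda: {"n_boot": 2000})
    stacking: dict = field(default_factory=dict)    # StackingConfig overrides
    cpi: dict = field(default_factory=lambda: {"n_perm": 500})
    force: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def digest(self) -> str:
        items = sorted((k, repr(v)) for k, v in self.__dict__.items()
                       if k != "force")
        return hashlib.sha256(repr(items).encode()).hexdigest()[:16]


def _substream(seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2 ** 31)


def run(config: RunConfig) -> dict:
    """Execute the requested stages in order; returns the manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    manifest = {"config_hash": config.digest(), "seed": config.seed,
                "stages": {}}
    if manifest_path.exists():
        try:
            prev = json.loads(manifest_path.read_text())
            if prev.get("config_hash") == manifest["config_hash"]:
                manifest = prev
        except json.JSONDecodeError:
            pass

    runners = {"simulate": _stage_simulate, "features": _stage_features,
               "manova": _stage_manova, "cluster": _stage_cluster,
               "model": _stage_model, "classify": _stage_classify,
               "cpi": _stage_cpi}
    for stage in config.stages:
        if stage not in runners:
            raise PipelineError(f"unknown stage {stage!r}")
        done = manifest["stages"].get(stage, {})
        outputs = [out / p for p in done.get("outputs", [])]
        if outputs and all(p.exists() for p in outputs) and not config.force:
            continue
        t0 = time.time()
        produced = runners[stage](config, out)
        manifest["stages"][stage] = {
            "outputs": [str(Path(p).relative_to(out)) for p in produced],
            "wall_time_s": round(time.time() - t0, 3)}
        manifest_path.write_text(json.dumps(manifest, indent=2))
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest


def _require(out: Path, name: str, stage: str) -> Path:
    p = out / name
    if not p.exists():
        raise PipelineError(
            f"stage {stage!r} requires missing artifact {name!r}; "
            "run the producing stage first")
    return p


def _cohort_spec(config: RunConfig) -> ch.CohortSpec:
    kw = dict(config.cohort)
    kw.setdefault("seed", _substream(config.seed, "simulate"))
    return ch.CohortSpec(**kw)


def _stage_simulate(config: RunConfig, out: Path):
    spec = _cohort_spec(config)
    layout = ch.make_layout(spec.n_sensors, spec.seed)
    cohort = ch.simulate_cohort(spec, layout)
    ch.write_cohort_csv(cohort, out / "cohort.csv")
    ch.write_signals_h5(cohort, spec, layout, out / "signals.h5")
    layout.to_json(out / "layout.json")
    return [out / "cohort.csv", out / "signals.h5", out / "layout.json"]


def _stage_features(config: RunConfig, out: Path):
    sig_path = _require(out, "signals.h5", "features")
    signals, attrs = ch.read_signals_h5(sig_path)
    fam = wv.build_wavelet_family(fs=float(attrs["fs"]), **config.wavelet)
    sensor_ids = [str(s) for s in attrs["sensor_ids"]]
    tensors = {sid: wv.compute_spectral_tensors(sig, fam,
                                                sensor_ids=sensor_ids)
               for sid, sig in signals.items()}
    wv.write_tensors_h5(out / "features.h5", tensors, fam.foi, sensor_ids)
    return [out / "features.h5"]


def _load_features(out: Path, stage: str):
    feat_path = _require(out, "features.h5", stage)
    tensors, foi, sensor_ids = wv.read_tensors_h5(feat_path)
    tab = pd.read_csv(_require(out, "cohort.csv", stage))
    ordered = [tensors[sid] for sid in tab["subject_id"]]
    labels = (tab["group"] == "progression").astype(int).to_numpy()
    return ordered, tab, labels, np.asarray(foi)


def _stage_manova(config: RunConfig, out: Path):
    tensors, tab, labels, foi = _load_features(out, "manova")
    s = config.stats
    produced = []
    t0 = tensors[0]
    usable = np.array([t0.cov is not None and not np.isnan(t0.cov[i]).any()
                       for i in range(len(foi))])
    for metric in s.get("metrics", ["cov"]):
        sets, foi_used = [], []
        for fi in np.where(usable)[0]:
            if metric == "dwpli":
                mats = np.stack([t.dwpli[fi] for t in tensors])
                sets.append(spd.dwpli_to_spd(mats, rank=s.get("dwpli_rank", 5)))
            else:
                attr = "cov" if metric == "cov" else "env_corr"
                mats = np.stack([getattr(t, attr)[fi] for t in tensors])
                rank = min(s.get("rank", 65), mats.shape[-1])
                sets.append(spd.common_subspace_project(mats, rank))
            foi_used.append(foi[fi])
        res = spd.distance_manova(sets, labels, n_perm=s.get("n_perm", 1000),
                                  rng=_substream(config.seed, "manova"),
                                  foi=foi_used)
        path = out / f"manova_{metric}.csv"
        res.to_frame().to_csv(path, index=False)
        produced.append(path)
    return produced


def _stage_cluster(config: RunConfig, out: Path):
    tensors, tab, labels, foi = _load_features(out, "cluster")
    layout = ch.SensorLayout.from_json(_require(out, "layout.json", "cluster"))
    s = config.stats
    logp = np.stack([t.log_psd for t in tensors])          # (n, S, F)
    ok = ~np.isnan(logp[0]).any(axis=0)                    # usable freqs
    res = cl.tfce_permutation_test(
        logp[:, :, ok], labels, e=s.get("e", 0.5), h=s.get("h", 2.0),
        n_perm=s.get("n_perm", 1000), adjacency=layout.adjacency,
        alpha=s.get("alpha", 0.05),
        rng=_substream(config.seed, "cluster"))
    ss, ff = np.meshgrid(np.arange(logp.shape[1]), foi[ok], indexing="ij")
    df = pd.DataFrame({"sensor": ss.ravel(), "freq": ff.ravel(),
                       "t": res.t_obs.ravel(), "tfce": res.tfce.ravel(),
                       "p_corrected": res.p_corrected.ravel(),
                       "significant": res.sig_mask.ravel()})
    df.to_csv(out / "cluster_sensor_freq.csv", index=False)
    sig_full = np.zeros((logp.shape[1], len(foi)), bool)
    sig_full[:, ok] = res.sig_mask
    (out / "cluster_mask.json").write_text(json.dumps(
        {"sig_mask": sig_full.astype(int).tolist(),
         "alpha": res.alpha, "n_permutations": res.n_permutations}))
    return [out / "cluster_sensor_freq.csv", out / "cluster_mask.json"]


def _stage_model(config: RunConfig, out: Path):
    tensors, tab, labels, foi = _load_features(out, "model")
    layout = ch.SensorLayout.from_json(_require(out, "layout.json", "model"))
    logp = np.stack([t.log_psd for t in tensors])
    mask_path = out / "cluster_mask.json"
    cluster_result = None
    if mask_path.exists():
        d = json.loads(mask_path.read_text())
        sig = np.asarray(d["sig_mask"], bool)
        cluster_result = type("MaskOnly", (), {"sig_mask": sig})()
    cpv = risk.cluster_meg_power_variable(np.nan_to_num(logp), foi, layout,
                                          cluster_result)
    comp = risk.compare_models(tab, cluster_power=cpv.values,
                               n_boot=config.model.get("n_boot", 2000),
                               rng=_substream(config.seed, "model"))
    comp.to_csv(out / "model_comparison.csv", index=False)
    ames = []
    for mspec in risk.DEFAULT_MODELS:
        m = risk.ProgressionModel.from_cohort(tab, mspec, cpv.values)
        a = m.fit().ame().reset_index(names="predictor")
        a.insert(0, "model", mspec.name)
        ames.append(a)
    pd.concat(ames).to_csv(out / "marginal_effects.csv", index=False)
    return [out / "model_comparison.csv", out / "marginal_effects.csv"]


def _stacking_config(config: RunConfig) -> st.StackingConfig:
    kw = dict(config.stacking)
    kw.setdefault("seed", _substream(config.seed, "classify"))
    return st.StackingConfig(**kw)


def _stage_classify(config: RunConfig, out: Path):
    tensors, tab, labels, foi = _load_features(out, "classify")
    cfg = _stacking_config(config)
    blocks = st.build_blocks(tensors, tab, cfg, foi)
    result = st.StackedProgressionClassifier(blocks, labels, cfg).fit()
    result.summary().to_csv(out / "stacking_summary.csv", index=False)
    (out / "stacking_auc.json").write_text(json.dumps(
        {k: [None if not np.isfinite(x) else float(x) for x in v]
         for k, v in result.auc.items()}))
    # artifacts for the cpi stage are kept in-process only; cpi re-fits
    return [out / "stacking_summary.csv", out / "stacking_auc.json"]


def _stage_cpi(config: RunConfig, out: Path):
    tensors, tab, labels, foi = _load_features(out, "cpi")
    _require(out, "stacking_summary.csv", "cpi")
    cfg = _stacking_config(config)
    blocks = st.build_blocks(tensors, tab, cfg, foi)
    result = st.StackedProgressionClassifier(blocks, labels, cfg).fit()
    cpi = imp.conditional_permutation_importance(
        result, n_perm=config.cpi.get("n_perm", 500),
        rng=_substream(config.seed, "cpi"))
    cpi.to_frame().to_csv(out / "cpi.csv", index=False)
    return [out / "cpi.csv"]
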