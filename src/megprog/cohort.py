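"""Synthetic MCI cohort generator.

Generates a fully synthetic two-site cohort of MCI patients (AD progressors vs
stable) with the statistical structure the downstream analyses expect:

* epoched multichannel sensor time series with a 1/f background, a ~10 Hz
  posterior alpha rhythm, and a set of planted group effects -- a posterior
  16-38 Hz power reduction in progressors, a low-frequency (delta-theta)
  sensor-covariance difference with matched per-sensor power, a 90 deg
  phase-lagged ~9 Hz source pair whose coupling differs between groups, and a
  source pair with shared slow power envelopes whose envelope correlation
  differs between groups;
* demographics (age, education, MMSE, sex) drawn from group-specific Gaussians
  matching the published cohort summary;
* regional brain volumes with a single planted atrophy effect (the hippocampal
  volume / total grey matter ratio, lower in progressors);
* exact site-by-group counts and a fixed pattern of missing values
  (education, MMSE, whole MRI blocks).

Everything is a pure function of :class:`CohortSpec` (including its seed).
"""

from __future__ import annotations

import copy
import dataclasses
import json
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd
from scipy import signal as sps

GROUPS = ("progression", "stable")
SITES = ("CTB", "CBU")

#: Group-wise demographic parameters: mean/SD of age, education, MMSE, male
#: fraction and the MMSE clipping range, as published for the two outcomes.
DEFAULT_DEMOGRAPHICS = {
    "progression": {
        "age": (73.03, 6.98),
        "education": (10.24, 4.54),
        "mmse": (25.54, 2.82),
        "mmse_range": (17.0, 30.0),
        "male_frac": 32 / 64,
    },
    "stable": {
        "age": (72.47, 5.32),
        "education": (8.58, 4.50),
        "mmse": (27.15, 2.41),
        "mmse_range": (22.0, 30.0),
        "male_frac": 20 / 53,
    },
}

#: Hippocampal-ratio and regional-volume parameters.  The hippocampus is
#: region 0 of the 64 atlas regions and carries the only planted MRI effect
#: (lower ratio in progressors, ~1 SD -- the scale reported for hippocampal
#: atrophy in MCI converters); the other 63 regions are exchangeable
#: Gaussian nuisance dimensions.
DEFAULT_MRI = {
    "progression": {"hippo_ratio": (0.0048, 0.0008)},
    "stable": {"hippo_ratio": (0.0058, 0.0008)},
    "total_gm": (600_000.0, 50_000.0),     # mm^3
    "region": (10_000.0, 1_500.0),         # mm^3, i.i.d. across 63 regions
    "n_regions": 64,
    #: mild distributed atrophy in progressors: regions 1..n_atrophy shifted
    #: down by this many mm^3 (~0.4 SD), mirroring the temporo-parietal
    #: atrophy pattern of MCI converters beyond the hippocampus
    "n_atrophy_regions": 8,
    "atrophy_shift": 600.0,
}


class CohortError(ValueError):
    """Invalid cohort specification or request."""


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of the synthetic cohort.

    The defaults reproduce the published cohort: 64 progressors / 53 stable
    MCI patients split unevenly over the Madrid (CTB) and Cambridge (CBU)
    sites, 2 min of resting-state data per subject as 12 x 10 s epochs at
    250 Hz over 102 sensors, and the published missing-value counts.
    """

    n_prog: int = 64
    n_stable: int = 53
    #: ``{(site, group): count}``; must sum to ``n_prog + n_stable``.
    site_table: dict = field(default_factory=lambda: {
        ("CTB", "progression"): 41, ("CTB", "stable"): 49,
        ("CBU", "progression"): 23, ("CBU", "stable"): 4,
    })
    demographic_params: dict = field(
        default_factory=lambda: {g: dict(DEFAULT_DEMOGRAPHICS[g]) for g in GROUPS})
    mri_params: dict = field(default_factory=lambda: copy.deepcopy(DEFAULT_MRI))

    # Planted signal effects (see module docstring). Fractions in [0, 1].
    beta_power_reduction: float = 0.4
    lowfreq_cov_shift: float = 0.4
    alpha_plv_shift: float = 0.10
    env_corr_shift: float = 0.2

    missing_education: int = 15
    missing_mmse: int = 5
    missing_mri: int = 13

    n_epochs: int = 12
    epoch_len_s: float = 10.0
    fs: float = 250.0
    n_sensors: int = 102
    seed: int = 0

    def __post_init__(self):
        total = self.n_prog + self.n_stable
        if sum(self.site_table.values()) != total:
            raise CohortError("site_table counts must sum to n_prog + n_stable")
        for g, n in (("progression", self.n_prog), ("stable", self.n_stable)):
            got = sum(v for (s, gg), v in self.site_table.items() if gg == g)
            if got != n:
                raise CohortError(f"site_table {g} counts sum to {got}, expected {n}")
        if min([self.n_prog, self.n_stable, *self.site_table.values()]) < 0:
            raise CohortError("counts must be nonnegative")
        n_samp = self.fs * self.epoch_len_s
        if abs(n_samp - round(n_samp)) > 1e-9:
            raise CohortError("fs * epoch_len_s must be an integer number of samples")
        for name in ("beta_power_reduction", "lowfreq_cov_shift",
                     "alpha_plv_shift", "env_corr_shift"):
            if not np.isfinite(getattr(self, name)):
                raise CohortError(f"effect size {name} must be finite")

    @property
    def n_subjects(self) -> int:
        return self.n_prog + self.n_stable

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.epoch_len_s))

    def scaled(self, **overrides) -> "CohortSpec":
        """Return a copy with overridden fields (counts must stay consistent)."""
        return dataclasses.replace(self, **overrides)


def reduced_spec(n_prog: int = 24, n_stable: int = 20, n_sensors: int = 24,
                 n_epochs: int = 5, epoch_len_s: float = 4.0, fs: float = 250.0,
                 seed: int = 0, **overrides) -> CohortSpec:
    """A down-scaled spec for simulation studies, preserving the default
    progressor/stable imbalance and site structure proportions."""
    ctb_p = int(round(n_prog * 41 / 64))
    cbu_p = n_prog - ctb_p
    ctb_s = int(round(n_stable * 49 / 53))
    cbu_s = n_stable - ctb_s
    n = n_prog + n_stable
    miss = {"missing_education": min(15, n // 8), "missing_mmse": min(5, n // 16),
            "missing_mri": min(13, n // 8)}
    miss.update({k: overrides.pop(k) for k in list(overrides)
                 if k.startswith("missing_")})
    return CohortSpec(
        n_prog=n_prog, n_stable=n_stable,
        site_table={("CTB", "progression"): ctb_p, ("CTB", "stable"): ctb_s,
                    ("CBU", "progression"): cbu_p, ("CBU", "stable"): cbu_s},
        n_sensors=n_sensors, n_epochs=n_epochs, epoch_len_s=epoch_len_s,
        fs=fs, seed=seed, **miss, **overrides)


# ---------------------------------------------------------------------------
# Sensor layout
# ---------------------------------------------------------------------------

@dataclass
class SensorLayout:
    """Flattened 2D sensor array on the unit disc (stand-in for a whole-head
    magnetometer layout).  ``posterior_mask`` marks the parieto-occipital
    subset (low y coordinate); ``adjacency`` is a symmetric neighbour relation
    built from inter-sensor distance."""

    sensor_ids: list
    positions: np.ndarray          # (n, 2)
    posterior_mask: np.ndarray     # (n,) bool
    adjacency: np.ndarray          # (n, n) bool, empty diagonal

    @property
    def n_sensors(self) -> int:
        return len(self.sensor_ids)

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump({"sensor_ids": list(self.sensor_ids),
                       "positions": self.positions.tolist(),
                       "posterior_mask": self.posterior_mask.astype(int).tolist(),
                       "adjacency": self.adjacency.astype(int).tolist()}, fh)

    @classmethod
    def from_json(cls, path):
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["sensor_ids"], np.asarray(d["positions"], float),
                   np.asarray(d["posterior_mask"], bool),
                   np.asarray(d["adjacency"], bool))


def make_layout(n_sensors: int = 102, seed: int = 0) -> SensorLayout:
    """Deterministic quasi-uniform disc layout with distance-threshold adjacency.

    The threshold is chosen by bisection so the mean neighbour count lands in
    [4, 8]; sensors left with fewer than 2 neighbours are connected to their
    2 nearest.  The posterior mask is the lowest ~30% of sensors by y.
    """
    if n_sensors < 4:
        raise CohortError("need at least 4 sensors")
    rng = np.random.default_rng(seed)
    # sunflower (Fibonacci) spiral + small seeded jitter
    k = np.arange(1, n_sensors + 1)
    r = np.sqrt((k - 0.5) / n_sensors)
    theta = k * np.pi * (3.0 - np.sqrt(5.0))
    pos = np.c_[r * np.cos(theta), r * np.sin(theta)]
    pos += rng.normal(scale=0.01, size=pos.shape)
    d = np.linalg.norm(pos[:, None] - pos[None], axis=-1)
    np.fill_diagonal(d, np.inf)

    lo, hi = 0.0, 2.5
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        mean_nb = (d < mid).sum(1).mean()
        if mean_nb < 6.0:
            lo = mid
        else:
            hi = mid
    adj = d < 0.5 * (lo + hi)
    # guarantee >= 2 neighbours each
    order = np.argsort(d, axis=1)
    for i in np.where(adj.sum(1) < 2)[0]:
        for j in order[i, :2]:
            adj[i, j] = adj[j, i] = True
    adj = adj | adj.T
    np.fill_diagonal(adj, False)

    cut = np.quantile(pos[:, 1], 0.30)
    posterior = pos[:, 1] <= cut
    ids = [f"MEG{i:03d}" for i in range(n_sensors)]
    return SensorLayout(ids, pos, posterior, adj)


def smooth_field(layout: SensorLayout, rng: np.random.Generator,
                 n_bumps: int = 5, width: float = 0.45,
                 mask: np.ndarray | None = None) -> np.ndarray:
    """Spatially smooth random mixing vector over the layout: a signed sum of
    Gaussian bumps, optionally concentrated on ``mask`` (with 10% leakage so
    fields spread beyond the mask as real sensor topographies do)."""
    centers = rng.uniform(-1, 1, size=(n_bumps, 2))
    amps = rng.normal(size=n_bumps)
    d2 = ((layout.positions[:, None] - centers[None]) ** 2).sum(-1)
    v = (np.exp(-d2 / (2 * width ** 2)) * amps).sum(1)
    if mask is not None:
        v = np.abs(v) * (mask.astype(float) + 0.1)
    n = np.linalg.norm(v)
    return v / n if n > 0 else v


@dataclass
class SpatialModel:
    """Cohort-level mixing vectors (fixed across subjects so planted effects
    are consistent group-level topographies)."""

    alpha_mix: np.ndarray
    beta_mix: np.ndarray
    lf_mix: np.ndarray             # (n_sensors, 2) baseline delta-theta pair
    lf_mix_shifted: np.ndarray     # perturbed pair, per-sensor power matched
    plv_mix_a: np.ndarray
    plv_mix_b: np.ndarray
    env_mix_a: np.ndarray
    env_mix_b: np.ndarray


def build_spatial_model(spec: CohortSpec, layout: SensorLayout) -> SpatialModel:
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 917]))
    post = layout.posterior_mask
    # broad posterior topographies (wide bumps), mirroring the spatially
    # extended posterior alpha/beta fields seen in resting-state data
    alpha_mix = smooth_field(layout, rng, width=0.9, mask=post)
    beta_mix = smooth_field(layout, rng, width=0.9, mask=post)
    a1 = smooth_field(layout, rng)
    a2 = smooth_field(layout, rng)
    lf = np.c_[a1, a2]
    # perturb the second mixing vector, then rescale each sensor's total
    # low-frequency gain back so the per-sensor power is matched and only
    # the cross-sensor covariance structure changes
    b = smooth_field(layout, rng)
    a2s = a2 + spec.lowfreq_cov_shift * b
    lf_s = np.c_[a1, a2s]
    pow0 = (lf ** 2).sum(1)
    pow1 = (lf_s ** 2).sum(1)
    scale = np.sqrt(pow0 / np.maximum(pow1, 1e-30))
    lf_s = lf_s * scale[:, None]
    plv_a = smooth_field(layout, rng)
    plv_b = smooth_field(layout, rng)
    env_a = smooth_field(layout, rng)
    env_b = smooth_field(layout, rng)
    return SpatialModel(alpha_mix, beta_mix, lf, lf_s, plv_a, plv_b, env_a, env_b)


# ---------------------------------------------------------------------------
# Subject records
# ---------------------------------------------------------------------------

@dataclass
class SubjectRecord:
    subject_id: str
    group: str
    site: str
    sex: str                        # "M" / "F"
    age: float
    education: float | None
    mmse: float | None
    signals: np.ndarray | None      # (epochs, sensors, samples) or None
    mri_volumes: np.ndarray | None  # (64,) regional volumes, or None
    total_gm: float | None
    hippo_volume: float | None

    @property
    def hippocampal_ratio(self) -> float | None:
        if self.hippo_volume is None or self.total_gm is None:
            return None
        return self.hippo_volume / self.total_gm


def _one_over_f(rng, n_epochs, n_sensors, n_samp, fs, exponent=1.0):
    """Spectrally shaped white noise with power spectrum ~ 1/f**exponent,
    unit variance per sensor."""
    w = rng.standard_normal((n_epochs, n_sensors, n_samp))
    freqs = np.fft.rfftfreq(n_samp, 1 / fs)
    g = np.ones_like(freqs)
    nz = freqs > 0
    g[nz] = freqs[nz] ** (-exponent / 2)
    g[0] = g[1]
    spec_ = np.fft.rfft(w, axis=-1) * g
    x = np.fft.irfft(spec_, n=n_samp, axis=-1)
    # analytic unit-variance normalization for the shaping filter
    wgt = np.ones_like(g)
    wgt[0] = 0.5
    if n_samp % 2 == 0:
        wgt[-1] = 0.5
    norm = np.sqrt(2 * (wgt * g ** 2).sum() / n_samp)
    return x / norm


def _band_noise(rng, shape, band, fs):
    """4th-order Butterworth band-passed white noise, unit variance."""
    lo, hi = band
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(shape), axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    return x / np.maximum(sd, 1e-30)


def _slow_modulator(rng, shape, fs, cutoff=0.5):
    """Positive slow amplitude envelope (low-passed noise through softplus)."""
    sos = sps.butter(4, cutoff, btype="lowpass", fs=fs, output="sos")
    m = sps.sosfiltfilt(sos, rng.standard_normal(shape), axis=-1)
    m = m / np.maximum(m.std(axis=-1, keepdims=True), 1e-30)
    return np.log1p(np.exp(m))   # softplus keeps the envelope positive


# relative source amplitudes (background sigma = 1); see docs/methods.md
_AMP = {"alpha": 1.5, "beta": 1.2, "lowfreq": 1.0, "plv": 0.8, "env": 0.8}
_PLV_COUPLING = 0.9
_ENV_WEIGHT = 0.8
#: lognormal sigma of per-source amplitude jitter and of the global
#: per-subject gain (head size / SNR variability)
_JITTER_SD = 0.15
_GLOBAL_GAIN_SD = 0.2


def simulate_signals(spec: CohortSpec, layout: SensorLayout, model: SpatialModel,
                     group: str, rng: np.random.Generator) -> np.ndarray:
    """Epoched sensor signals for one subject.

    The group label enters only through multiplicative effect factors, so with
    all effect sizes at 0 the signal path is distributionally identical across
    groups (and sample-identical on a shared rng substream).
    """
    E, S, N, fs = spec.n_epochs, layout.n_sensors, spec.n_samples, spec.fs
    prog = group == "progression"

    x = _one_over_f(rng, E, S, N, fs)

    jitter = np.exp(rng.normal(0, _JITTER_SD, size=6))   # per-source jitter
    gain = np.exp(rng.normal(0, _GLOBAL_GAIN_SD))        # global subject gain

    # (ii) posterior alpha source ~10 Hz
    alpha = _band_noise(rng, (E, N), (8.0, 12.0), fs)
    x += _AMP["alpha"] * jitter[0] * model.alpha_mix[None, :, None] * alpha[:, None, :]

    # (iii) posterior 16-38 Hz source, reduced in progressors
    beta = _band_noise(rng, (E, N), (16.0, 38.0), fs)
    amp = _AMP["beta"] * jitter[1]
    if prog:
        amp *= 1.0 - spec.beta_power_reduction
    x += amp * model.beta_mix[None, :, None] * beta[:, None, :]

    # (iv) delta-theta source pair; group-dependent mixing, matched per-sensor power
    lf = _band_noise(rng, (E, 2, N), (1.0, 4.0), fs)
    mix = model.lf_mix_shifted if prog else model.lf_mix
    x += _AMP["lowfreq"] * jitter[2] * np.einsum("sk,ekn->esn", mix, lf)

    # (v) ~9 Hz pair with a fixed 90 deg phase lag; coupling differs by group
    src = _band_noise(rng, (E, N), (8.5, 9.5), fs)
    quad = np.imag(sps.hilbert(src, axis=-1))          # 90 deg shifted copy
    quad = quad / np.maximum(quad.std(axis=-1, keepdims=True), 1e-30)
    indep = _band_noise(rng, (E, N), (8.5, 9.5), fs)
    c = _PLV_COUPLING * ((1.0 - spec.alpha_plv_shift) if prog else 1.0)
    srcb = c * quad + np.sqrt(max(0.0, 1.0 - c ** 2)) * indep
    x += _AMP["plv"] * jitter[3] * (model.plv_mix_a[None, :, None] * src[:, None, :]
                                    + model.plv_mix_b[None, :, None] * srcb[:, None, :])

    # (vi) pair of independent ~12 Hz carriers with shared slow envelopes
    m_common = _slow_modulator(rng, (E, N), fs)
    m1 = _slow_modulator(rng, (E, N), fs)
    m2 = _slow_modulator(rng, (E, N), fs)
    w = _ENV_WEIGHT * ((1.0 - spec.env_corr_shift) if prog else 1.0)
    env1 = np.sqrt(w) * m_common + np.sqrt(1 - w) * m1
    env2 = np.sqrt(w) * m_common + np.sqrt(1 - w) * m2
    car1 = _band_noise(rng, (E, N), (11.0, 13.0), fs)
    car2 = _band_noise(rng, (E, N), (11.0, 13.0), fs)
    x += _AMP["env"] * jitter[4] * (
        model.env_mix_a[None, :, None] * (env1 * car1)[:, None, :]
        + model.env_mix_b[None, :, None] * (env2 * car2)[:, None, :])
    return gain * x


def simulate_subject(spec: CohortSpec, layout: SensorLayout, group: str,
                     site: str, rng: np.random.Generator,
                     model: SpatialModel | None = None, subject_id: str = "S000",
                     with_signals: bool = True) -> SubjectRecord:
    """Draw one subject (signals + demographics + MRI volumes)."""
    if group not in GROUPS:
        raise CohortError(f"unknown group {group!r}")
    if site not in SITES:
        raise CohortError(f"unknown site {site!r}")
    if model is None:
        model = build_spatial_model(spec, layout)

    signals = simulate_signals(spec, layout, model, group, rng) if with_signals else None

    dp = spec.demographic_params[group]
    sex = "M" if rng.uniform() < dp["male_frac"] else "F"
    age = rng.normal(*dp["age"])
    education = max(0.0, rng.normal(*dp["education"]))
    lo, hi = dp["mmse_range"]
    mmse = float(np.clip(rng.normal(*dp["mmse"]), lo, hi))

    mp = spec.mri_params
    total_gm = rng.normal(*mp["total_gm"])
    ratio = max(1e-4, rng.normal(*mp[group]["hippo_ratio"]))
    hippo = ratio * total_gm
    regions = rng.normal(*mp["region"], size=mp["n_regions"])
    regions[0] = hippo            # the hippocampus is one of the 64 regions
    if group == "progression":
        na = int(mp.get("n_atrophy_regions", 0))
        regions[1:1 + na] -= mp.get("atrophy_shift", 0.0)

    return SubjectRecord(subject_id, group, site, sex, float(age),
                         float(education), mmse, signals, regions,
                         float(total_gm), float(hippo))


def simulate_cohort(spec: CohortSpec, layout: SensorLayout | None = None,
                    with_signals: bool = True,
                    with_missingness: bool = True) -> list[SubjectRecord]:
    """Simulate the full cohort with exactly the site-by-group counts of the
    spec; reproducible from ``spec.seed``."""
    if layout is None:
        layout = make_layout(spec.n_sensors, spec.seed)
    model = build_spatial_model(spec, layout)
    ss = np.random.SeedSequence([spec.seed, 101])
    children = ss.spawn(spec.n_subjects)
    cohort, i = [], 0
    for site in SITES:
        for group in GROUPS:
            for _ in range(spec.site_table.get((site, group), 0)):
                rng = np.random.default_rng(children[i])
                cohort.append(simulate_subject(
                    spec, layout, group, site, rng, model,
                    subject_id=f"S{i:03d}", with_signals=with_signals))
                i += 1
    if with_missingness:
        cohort = inject_missingness(cohort, spec)
    return cohort


def inject_missingness(cohort: list[SubjectRecord], spec: CohortSpec) -> list[SubjectRecord]:
    """Blank exactly the specified numbers of education, MMSE and whole-MRI
    values, uniformly at random from the seeded stream.  Group labels are
    never blanked."""
    n = len(cohort)
    for name, cnt in (("missing_education", spec.missing_education),
                      ("missing_mmse", spec.missing_mmse),
                      ("missing_mri", spec.missing_mri)):
        if cnt > n:
            raise CohortError(f"{name}={cnt} exceeds cohort size {n}")
        if cnt < 0:
            raise CohortError(f"{name} must be nonnegative")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 7751]))
    idx_edu = rng.choice(n, size=spec.missing_education, replace=False)
    idx_mmse = rng.choice(n, size=spec.missing_mmse, replace=False)
    idx_mri = rng.choice(n, size=spec.missing_mri, replace=False)
    for i in idx_edu:
        cohort[i].education = None
    for i in idx_mmse:
        cohort[i].mmse = None
    for i in idx_mri:
        cohort[i].mri_volumes = None
        cohort[i].total_gm = None
        cohort[i].hippo_volume = None
    return cohort


# ---------------------------------------------------------------------------
# Tabular / file interfaces
# ---------------------------------------------------------------------------

def cohort_table(cohort: list[SubjectRecord]) -> pd.DataFrame:
    """One row per subject; missing fields are NaN. Regional volumes appear as
    ``vol_000`` ... columns."""
    rows = []
    for s in cohort:
        row = {"subject_id": s.subject_id, "group": s.group, "site": s.site,
               "sex": s.sex, "age": s.age,
               "education": np.nan if s.education is None else s.education,
               "mmse": np.nan if s.mmse is None else s.mmse,
               "total_gm": np.nan if s.total_gm is None else s.total_gm,
               "hippo_volume": np.nan if s.hippo_volume is None else s.hippo_volume,
               "hippocampal_ratio": (np.nan if s.hippocampal_ratio is None
                                     else s.hippocampal_ratio)}
        nv = len(s.mri_volumes) if s.mri_volumes is not None else 64
        for j in range(nv):
            row[f"vol_{j:03d}"] = (np.nan if s.mri_volumes is None
                                   else s.mri_volumes[j])
        rows.append(row)
    return pd.DataFrame(rows)


def write_cohort_csv(cohort, path):
    cohort_table(cohort).to_csv(path, index=False)


def write_signals_h5(cohort, spec: CohortSpec, layout: SensorLayout, path):
    with h5py.File(path, "w") as fh:
        fh.attrs["fs"] = spec.fs
        fh.attrs["epoch_len_s"] = spec.epoch_len_s
        fh.attrs["sensor_ids"] = [str(s) for s in layout.sensor_ids]
        for s in cohort:
            if s.signals is not None:
                fh.create_dataset(s.subject_id, data=s.signals)


def read_signals_h5(path):
    """Return ``(dict subject_id -> signals, attrs)``."""
    out, attrs = {}, {}
    with h5py.File(path, "r") as fh:
        attrs = dict(fh.attrs)
        for k in fh:
            out[k] = fh[k][()]
    return out, attrs
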