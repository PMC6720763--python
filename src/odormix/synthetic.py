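"""Synthetic sensory-panel and e-nose data with known generating truth.

No public dataset accompanies this problem: panel ratings and raw sensor
signals live only with the original hardware.  This module generates both
with the statistical structure the pipeline assumes, always returning the
generating parameters ("truth") alongside the data so every estimator in
the package can be exercised as a parameter-recovery problem.

* **Panel ratings** follow the odorant's Weber–Fechner law plus Gaussian
  rating noise, rounded to the integer VDI scale and clamped to [0, 6] —
  emulating a trained panel (default rating noise sd 0.3 OI units,
  triplicate mixture ratings, as in the sensory designs the estimators
  target).
* **Mixture intensities** come from a chosen perceptual model with a
  specified cosα matrix, at components generated to sit exactly at an
  integer intensity level.
* **Sensor signals** use a log-saturating MOS-like response
  ``baseline + Σ_o a_{s,o}·log10(1 + c_o/κ_{s,o})`` with additive Gaussian
  noise and a multiplicative suppression factor (1 − γ_s) applied to the
  summed response when two or more odorants are present — the simplest
  structure that makes mixture signals non-additive.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .fuzzy import LabeledSample
from .perceptual import InteractionMatrix, predict_mixture
from .psychophysics import OdorantProfile, concentration_for_oi, oi_from_concentration

__all__ = [
    "PanelModel",
    "SensorModel",
    "SyntheticDataset",
    "default_sensor_model",
    "doubling_series",
    "simulate_single_odorant_panel",
    "simulate_binary_mixture_panel",
    "simulate_enose_signals",
    "simulate_enose_training",
    "make_fixture_suite",
]

#: Default 8-channel array layout mirroring a PID + electrochemical + MOS prototype.
DEFAULT_SENSORS = ("S1", "S2", "S3", "S4", "S5", "S6", "S7", "S8")


@dataclass(frozen=True)
class PanelModel:
    """Statistical model of the sensory panel.

    Ratings are ``clamp(round(true_oi + noise), 0, 6)``: continuous truth,
    Gaussian rater noise, integer VDI reporting.
    """

    noise_sd: float = 0.3
    n_replicates: int = 3
    clamp: tuple[float, float] = (0.0, 6.0)

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def rate(self, true_oi: float, rng: np.random.Generator, size=None):
        noisy = true_oi + rng.normal(0.0, self.noise_sd, size=size) \
            if self.noise_sd > 0 else true_oi + np.zeros(size if size else 1)
        lo, hi = self.clamp
        return np.clip(np.round(noisy), lo, hi)


@dataclass(frozen=True)
class SensorModel:
    """Parametric response model for the sensor array.

    ``sensitivity[s][o]`` (signal units per decade) and ``scale[s][o]``
    (ppm) shape the log-saturating response of sensor ``s`` to odorant
    ``o``; ``suppression[s]`` in [0, 1) attenuates the summed response when
    a mixture is present; ``noise_sd`` is additive signal noise.
    """

    baseline: Mapping[str, float]
    sensitivity: Mapping[str, Mapping[str, float]]
    scale: Mapping[str, Mapping[str, float]]
    suppression: Mapping[str, float]
    noise_sd: float = 0.02

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for s in self.sensors:
            if not 0.0 <= self.suppression[s] < 1.0:
                raise ValueError("suppression must lie in [0, 1)")
            if any(k <= 0 for k in self.scale[s].values()):
                raise ValueError("scale parameters must be > 0")

    @property
    def sensors(self) -> list[str]:
        return list(self.baseline)

    def respond(self, concentrations: Mapping[str, float],
                rng: np.random.Generator | None = None) -> dict[str, float]:
        """Noise-free unless an rng is supplied."""
        active = sum(1 for c in concentrations.values() if c > 0)
        out = {}
        for s in self.sensors:
            resp = sum(self.sensitivity[s][o] * np.log10(1.0 + c / self.scale[s][o])
                       for o, c in concentrations.items())
            if active >= 2:
                resp *= 1.0 - self.suppression[s]
            value = self.baseline[s] + resp
            if rng is not None and self.noise_sd > 0:
                value += rng.normal(0.0, self.noise_sd)
            out[s] = float(value)
        return out


@dataclass(frozen=True)
class SyntheticDataset:
    """Generated samples plus the full generating truth and seed."""

    samples: pd.DataFrame
    truth: dict
    seed: int


def default_sensor_model(profiles: Sequence[OdorantProfile],
                         noise_sd: float = 0.02,
                         sensors: Sequence[str] = DEFAULT_SENSORS) -> SensorModel:
    """A deterministic, broadly selective default array parameterization.

    Sensitivities and scales are drawn once from a fixed-seed generator
    (the same profiles always give the same model): sensitivities span
    roughly 0.4–1.6 signal units per decade, response scales sit between
    2× and 16× each odorant's threshold so the five VDI levels fall on the
    informative part of the log response, and suppression factors span
    0.05–0.25 across channels.
    """
    rng = np.random.default_rng(1203)
    baseline, sens, scale, supp = {}, {}, {}, {}
    for i, s in enumerate(sensors):
        baseline[s] = float(0.05 + 0.02 * i)
        supp[s] = float(0.05 + 0.20 * i / max(len(sensors) - 1, 1))
        sens[s] = {}
        scale[s] = {}
        for p in profiles:
            sens[s][p.name] = float(rng.uniform(0.4, 1.6))
            scale[s][p.name] = float(p.wf.c_ot * 10 ** rng.uniform(0.3, 1.2))
    return SensorModel(baseline=baseline, sensitivity=sens, scale=scale,
                       suppression=supp, noise_sd=noise_sd)


def doubling_series(base: float, n: int = 5) -> list[float]:
    """The standard panel design: n concentrations, each 2× the previous."""
    if base <= 0 or n < 1:
        raise ValueError("base must be > 0 and n >= 1")
    return [base * 2.0**k for k in range(n)]


def simulate_single_odorant_panel(profile: OdorantProfile,
                                  concentrations: Sequence[float] | None = None,
                                  panel: PanelModel = PanelModel(),
                                  n_panelists: int = 10,
                                  seed: int = 0) -> SyntheticDataset:
    """Panel ratings of one odorant over a concentration series.

    Default design: five two-fold increasing concentrations starting at the
    odorant's OI=1 concentration, rated by ``n_panelists`` panelists.  True
    intensity follows the profile's Weber–Fechner law.
    """
    if concentrations is None:
        concentrations = doubling_series(concentration_for_oi(profile.wf, 1.0), 5)
    if any(c <= 0 for c in concentrations):
        raise ValueError("concentrations must be > 0")
    rng = np.random.default_rng(seed)
    rows = []
    true_oi = {}
    for c in concentrations:
        oi = float(oi_from_concentration(profile.wf, c))
        true_oi[c] = oi
        ratings = panel.rate(oi, rng, size=n_panelists)
        for j, r in enumerate(np.atleast_1d(ratings)):
            rows.append({"odorant": profile.name, "concentration_ppm": c,
                         "panelist_id": f"p{j + 1:02d}", "oi": float(r)})
    df = pd.DataFrame(rows, columns=["odorant", "concentration_ppm", "panelist_id", "oi"])
    truth = {"law": {"k_wf": profile.wf.k_wf, "c_ot": profile.wf.c_ot},
             "true_oi": true_oi, "panel": {"noise_sd": panel.noise_sd},
             "n_panelists": n_panelists}
    return SyntheticDataset(samples=df, truth=truth, seed=seed)


def simulate_binary_mixture_panel(profiles: Sequence[OdorantProfile],
                                  cos_matrix: InteractionMatrix,
                                  model: str,
                                  oi_level: float,
                                  panel: PanelModel = PanelModel(),
                                  seed: int = 0) -> SyntheticDataset:
    """Triplicate panel ratings of every pairwise mixture at one OI level.

    Component concentrations are set so each component alone sits exactly
    at ``oi_level``; the true mixture intensity comes from the chosen
    perceptual model with the pair's cosα.  A missing pair coefficient is
    an error.
    """
    rng = np.random.default_rng(seed)
    rows = []
    truth_cos = {}
    profs = list(profiles)
    for i, pa in enumerate(profs):
        for pb in profs[i + 1:]:
            if (pa.name, pb.name) not in cos_matrix:
                raise KeyError(f"no cosα for pair ({pa.name}, {pb.name})")
            cos = cos_matrix.cos(pa.name, pb.name)
            true_ab = predict_mixture(model, oi_level, oi_level, cos)
            truth_cos[(pa.name, pb.name)] = cos
            c_a = concentration_for_oi(pa.wf, oi_level)
            c_b = concentration_for_oi(pb.wf, oi_level)
            ratings = panel.rate(true_ab, rng, size=panel.n_replicates)
            for rep, r in enumerate(np.atleast_1d(ratings), start=1):
                rows.append({
                    "odorant_a": pa.name, "odorant_b": pb.name,
                    "c_a_ppm": c_a, "c_b_ppm": c_b,
                    "oi_a": float(oi_level), "oi_b": float(oi_level),
                    "true_oi_ab": true_ab, "replicate": rep, "rating": float(r),
                })
    df = pd.DataFrame(rows)
    truth = {"model": model, "oi_level": oi_level,
             "cos": {f"{a}|{b}": v for (a, b), v in truth_cos.items()},
             "panel": {"noise_sd": panel.noise_sd,
                       "n_replicates": panel.n_replicates}}
    return SyntheticDataset(samples=df, truth=truth, seed=seed)


def simulate_enose_signals(concentrations: Mapping[str, float],
                           sensor_model: SensorModel,
                           seed: int | None = None) -> dict[str, float]:
    """Sensor-array response to one gas sample (noise-free if seed is None)."""
    if any(c < 0 for c in concentrations.values()):
        raise ValueError("concentrations must be >= 0")
    rng = np.random.default_rng(seed) if seed is not None else None
    return sensor_model.respond(concentrations, rng=rng)


def simulate_enose_training(profiles: Sequence[OdorantProfile],
                            sensor_model: SensorModel,
                            levels: Sequence[int] = range(1, 6),
                            n_per_level: int = 3,
                            noise: bool = True,
                            seed: int = 0) -> list[LabeledSample]:
    """Labeled single-odorant array samples at each VDI level.

    For every odorant and level, ``n_per_level`` replicate samples are
    generated at the concentration placing that odorant alone at the level
    (Weber–Fechner inverse).  With ``noise=False`` the replicates are
    identical and calibration falls back to its sd floor.
    """
    rng = np.random.default_rng(seed)
    out = []
    for p in profiles:
        for level in levels:
            c = concentration_for_oi(p.wf, float(level))
            for rep in range(n_per_level):
                sig = sensor_model.respond(
                    {p.name: c}, rng=rng if noise and sensor_model.noise_sd > 0 else None)
                out.append(LabeledSample(
                    signals=sig, oi_label=int(level),
                    sample_id=f"{p.name}-L{level}-r{rep + 1}"))
    return out


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def make_fixture_suite(seed: int, outdir) -> dict:
    """Write the standard CSV/JSON fixture suite and its manifest.

    Produces, deterministically from ``seed``: the odorant profile JSON,
    single-odorant panel CSVs for all eight reference odorants, binary
    mixture panel CSVs at intensity levels 1 and 2 (all 28 pairs,
    triplicate), an e-nose training CSV (levels 1–5), and a
    ``manifest.json`` recording parameters, the seed, and sha256 checksums
    of every file.  Returns the manifest dict.
    """
    from pathlib import Path

    from .reference import reference_cos_matrix, reference_profiles

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    profiles = reference_profiles()

    files: dict[str, Path] = {}

    prof_json = outdir / "odorant_profiles.json"
    prof_json.write_text(json.dumps({
        p.name: {"molar_mass": p.molar_mass, "density_liquid": p.density_liquid,
                 "vapor_pressure": p.vapor_pressure,
                 "odor_threshold_lit": p.odor_threshold_lit,
                 "k_wf": p.wf.k_wf, "c_ot": p.wf.c_ot,
                 "n": p.stevens.n, "k_s": p.stevens.k_s}
        for p in profiles}, indent=2, sort_keys=True))
    files["odorant_profiles.json"] = prof_json

    panel_frames = [
        simulate_single_odorant_panel(p, seed=seed + i).samples
        for i, p in enumerate(profiles)
    ]
    panel_csv = outdir / "panel_single_odorant.csv"
    pd.concat(panel_frames, ignore_index=True).to_csv(panel_csv, index=False)
    files["panel_single_odorant.csv"] = panel_csv

    for level in (1, 2):
        cos = reference_cos_matrix("vectorial", oi_level=level)
        ds = simulate_binary_mixture_panel(profiles, cos, "vectorial", level,
                                           seed=seed + 100 + level)
        path = outdir / f"panel_mixtures_level{level}.csv"
        ds.samples.to_csv(path, index=False)
        files[f"panel_mixtures_level{level}.csv"] = path

    sensor_model = default_sensor_model(profiles)
    training = simulate_enose_training(profiles, sensor_model, seed=seed + 500)
    rows = []
    for samp in training:
        row = {"sample_id": samp.sample_id, "oi_label": samp.oi_label}
        row.update(samp.signals)
        rows.append(row)
    enose_csv = outdir / "enose_training.csv"
    pd.DataFrame(rows).to_csv(enose_csv, index=False)
    files["enose_training.csv"] = enose_csv

    manifest = {
        "seed": seed,
        "n_odorants": len(profiles),
        "n_pairs": len(profiles) * (len(profiles) - 1) // 2,
        "files": {name: _sha256(path) for name, path in files.items()},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
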