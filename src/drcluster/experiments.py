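"""Synthetic experimental datasets with known ground truth.

Generators for the three quantification assays: FRAP intensity traces
(FRAP / reference / background ROIs with acquisition photobleaching and a
single-exponential recovery of known mobile fraction and half-time),
mass-photometry event lists (Gaussian mixtures in kDa), and single-site
fluorescence-anisotropy binding curves with known Kd.  All generators are
seeded and bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class FrapTraces:
    """Raw three-ROI FRAP time series plus acquisition metadata."""

    time_s: np.ndarray
    frap: np.ndarray
    reference: np.ndarray
    background: np.ndarray
    bleach_frame: int            # index of the first post-bleach frame
    w_um: float                  # bleach spot radius
    ground_truth: dict | None = None

    def __post_init__(self):
        n = len(self.time_s)
        if not (len(self.frap) == len(self.reference) == len(self.background) == n):
            raise ValueError("all traces must have equal length")
        if not 0 < self.bleach_frame < n:
            raise ValueError("bleach frame must lie within the series")
        if self.w_um <= 0:
            raise ValueError("bleach spot radius must be positive")

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "time_s": self.time_s,
                "frap": self.frap,
                "reference": self.reference,
                "background": self.background,
            }
        ).to_csv(path, index=False)
        meta = {"bleach_frame": self.bleach_frame, "w_um": self.w_um}
        if self.ground_truth:
            meta["ground_truth"] = self.ground_truth
        Path(str(path) + ".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def from_csv(cls, path: str | Path) -> "FrapTraces":
        df = pd.read_csv(path)
        required = {"time_s", "frap", "reference", "background"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"FRAP CSV missing columns: {sorted(missing)}")
        meta = json.loads(Path(str(path) + ".json").read_text())
        return cls(
            time_s=df["time_s"].to_numpy(),
            frap=df["frap"].to_numpy(),
            reference=df["reference"].to_numpy(),
            background=df["background"].to_numpy(),
            bleach_frame=int(meta["bleach_frame"]),
            w_um=float(meta["w_um"]),
            ground_truth=meta.get("ground_truth"),
        )


def synth_frap(
    mobile_fraction: float,
    t_half_s: float,
    frame_interval_s: float = 5.0,
    n_frames: int = 122,
    bleach_frame: int = 2,
    bleach_decay_per_frame: float = 0.0,
    background_level: float = 100.0,
    noise_sd: float = 0.0,
    w_um: float = 2.0,
    amplitude: float = 1000.0,
    seed: int = 0,
) -> FrapTraces:
    """Three-ROI FRAP traces for a single-exponential recovery.

    Before the bleach the FRAP ROI sits at the pre-bleach plateau; from the
    bleach on it recovers as ``mobile_fraction * (1 - exp(-ln2 t/t_half))``
    above the fully-bleached floor.  All ROIs share the per-frame
    acquisition-bleach envelope ``(1 - bleach_decay)^frame`` and the
    background offset; Gaussian noise of the stated SD (in units of the
    pre-bleach amplitude) is added to every trace.
    """
    if not 0 <= mobile_fraction <= 1:
        raise ValueError("mobile fraction must be in [0, 1]")
    if t_half_s <= 0:
        raise ValueError("half-time must be positive")
    rng = np.random.default_rng(seed)
    t = np.arange(n_frames) * frame_interval_s
    envelope = (1 - bleach_decay_per_frame) ** np.arange(n_frames)
    k = np.log(2) / t_half_s
    recovery = np.ones(n_frames)
    post = np.arange(bleach_frame, n_frames)
    t_post = (post - bleach_frame) * frame_interval_s
    recovery[post] = mobile_fraction * (1 - np.exp(-k * t_post))
    frap = background_level + amplitude * envelope * recovery
    reference = background_level + amplitude * envelope
    background = np.full(n_frames, background_level, dtype=float)
    if noise_sd > 0:
        scale = noise_sd * amplitude
        frap = frap + rng.normal(0, scale, n_frames)
        reference = reference + rng.normal(0, scale, n_frames)
        background = background + rng.normal(0, scale, n_frames)
    return FrapTraces(
        time_s=t,
        frap=frap,
        reference=reference,
        background=background,
        bleach_frame=bleach_frame,
        w_um=w_um,
        ground_truth={
            "mobile_fraction": mobile_fraction,
            "t_half_s": t_half_s,
            "bleach_decay_per_frame": bleach_decay_per_frame,
            "noise_sd": noise_sd,
        },
    )


@dataclass
class MassSample:
    """Per-event masses (kDa) from mass photometry, after calibration."""

    masses: np.ndarray
    calibrated: bool = True
    ground_truth: list[dict] | None = None

    def __post_init__(self):
        # Measured calibrated masses must be positive; synthetic draws keep
        # their exact Gaussian tails (a broad component near the detection
        # limit may cross zero) so that fitted means stay unbiased.
        if self.calibrated and self.ground_truth is None and np.any(self.masses <= 0):
            raise ValueError("calibrated masses must be positive")

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"mass_kda": self.masses}).to_csv(path, index=False)
        if self.ground_truth is not None:
            Path(str(path) + ".json").write_text(
                json.dumps({"components": self.ground_truth}, indent=1)
            )

    @classmethod
    def from_csv(cls, path: str | Path) -> "MassSample":
        df = pd.read_csv(path)
        if "mass_kda" not in df.columns:
            raise ValueError("mass CSV must contain a 'mass_kda' column")
        ground_truth = None
        sidecar = Path(str(path) + ".json")
        if sidecar.exists():
            ground_truth = json.loads(sidecar.read_text()).get("components")
        return cls(masses=df["mass_kda"].to_numpy(), ground_truth=ground_truth)


def synth_masses(
    components: list[tuple[float, float, float]],  # (mean kDa, sd kDa, weight)
    n_events: int = 5000,
    seed: int = 0,
) -> MassSample:
    """Draw an event list from an (untruncated) Gaussian mixture."""
    weights = np.array([w for _, _, w in components], dtype=float)
    if not np.isclose(weights.sum(), 1.0):
        raise ValueError("component weights must sum to 1")
    if any(sd <= 0 for _, sd, _ in components):
        raise ValueError("component SDs must be positive")
    rng = np.random.default_rng(seed)
    which = rng.choice(len(components), size=n_events, p=weights)
    means = np.array([m for m, _, _ in components])[which]
    sds = np.array([s for _, s, _ in components])[which]
    masses = rng.normal(means, sds)
    return MassSample(
        masses=masses,
        ground_truth=[
            {"mean_kda": m, "sd_kda": s, "weight": w} for m, s, w in components
        ],
    )


@dataclass
class BindingCurve:
    """Single-site anisotropy binding curve."""

    concentration_um: np.ndarray
    anisotropy: np.ndarray
    ground_truth: dict | None = None
    ill_conditioned: bool = False

    def __post_init__(self):
        if len(self.concentration_um) != len(self.anisotropy):
            raise ValueError("concentration/anisotropy length mismatch")
        if np.any(self.concentration_um < 0):
            raise ValueError("concentrations must be >= 0")
        if len(np.unique(self.concentration_um)) != len(self.concentration_um):
            raise ValueError("concentrations must be distinct")

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "concentration_um": self.concentration_um,
                "anisotropy": self.anisotropy,
            }
        ).to_csv(path, index=False)
        if self.ground_truth is not None:
            Path(str(path) + ".json").write_text(json.dumps(self.ground_truth, indent=1))

    @classmethod
    def from_csv(cls, path: str | Path) -> "BindingCurve":
        df = pd.read_csv(path)
        required = {"concentration_um", "anisotropy"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"binding CSV missing columns: {sorted(missing)}")
        return cls(
            concentration_um=df["concentration_um"].to_numpy(),
            anisotropy=df["anisotropy"].to_numpy(),
        )


def synth_binding(
    kd_um: float,
    r0: float = 0.05,
    r_max: float = 0.25,
    conc_grid_um: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> BindingCurve:
    """Hyperbolic single-site binding curve ``r = r0 + (r_max - r0) L/(Kd + L)``.

    The curve is flagged ill-conditioned when the grid does not bracket Kd.
    """
    if kd_um <= 0:
        raise ValueError("Kd must be positive")
    if conc_grid_um is None:
        conc_grid_um = np.geomspace(kd_um / 40, kd_um * 50, 12)
    conc = np.asarray(conc_grid_um, dtype=float)
    rng = np.random.default_rng(seed)
    r = r0 + (r_max - r0) * conc / (kd_um + conc)
    if noise_sd > 0:
        r = r + rng.normal(0, noise_sd, len(conc))
    ill = not (conc.min() < kd_um < conc.max())
    return BindingCurve(
        concentration_um=conc,
        anisotropy=r,
        ground_truth={
            "kd_um": kd_um,
            "r0": r0,
            "r_max": r_max,
            "noise_sd": noise_sd,
        },
        ill_conditioned=ill,
    )
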