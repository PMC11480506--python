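"""Quantitative fits behind the experimental readouts.

* FRAP: three-ROI background/bleach correction and normalization, a
  one-phase-association fit ``Y(t) = Y0 + (Plateau - Y0)(1 - exp(-K t))``
  (optionally with no offset, Y0 = 0), and the Soumpasis closed form
  ``D = 0.224 w^2 / t_half`` for a uniform circular bleach spot in 2D.
* Mass photometry: linear contrast-to-mass calibration against a protein
  ladder (BSA monomer/dimer/trimer by default) and a Gaussian-mixture fit
  of the event-mass distribution with oligomer assignment.
* Binding: single-site hyperbolic anisotropy isotherm
  ``r(L) = r0 + (r_max - r0) L / (Kd + L)``.

All fits use fixed, documented initializations — no random restarts — so
results are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import linregress
from sklearn.mixture import GaussianMixture

from .experiments import BindingCurve, FrapTraces, MassSample

#: Soumpasis prefactor for a uniform circular bleach spot, 2D diffusion.
SOUMPASIS_COEFF = 0.224

#: BSA ladder (monomer/dimer/trimer), sequence mass of the mature chain.
BSA_LADDER_KDA = (66.4, 132.8, 199.2)


class FitError(RuntimeError):
    pass


class ProcessingError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# FRAP

def process_frap(traces: FrapTraces) -> tuple[np.ndarray, np.ndarray]:
    """Background-subtract, bleach-correct and normalize a FRAP trace.

    Returns ``(t, y)`` with t measured from the bleach; the first
    post-bleach point is 0 and the pre-bleach plateau 1 by construction.
    """
    b = traces.bleach_frame
    if b < 2:
        raise ProcessingError("need >= 2 pre-bleach frames")
    frap = traces.frap - traces.background
    ref = traces.reference - traces.background
    if np.any(ref <= 0):
        raise ProcessingError(
            "reference trace crosses zero after background subtraction"
        )
    factor = ref / np.mean(ref[:b])
    corrected = frap / factor
    pre = np.mean(corrected[:b])
    first_post = corrected[b]
    denom = pre - first_post
    if denom <= 0:
        raise ProcessingError("no bleach depth: pre-bleach <= first post-bleach")
    y = (corrected[b:] - first_post) / denom
    t = traces.time_s[b:] - traces.time_s[b]
    return t, y


@dataclass
class FrapFit:
    y0: float
    plateau: float
    k: float                      # 1/s
    mobile_fraction: float
    rss: float
    converged: bool
    clipped: bool = False
    d_um2_s: float | None = None
    message: str = ""

    @property
    def t_half_s(self) -> float:
        return float(np.log(2) / self.k)


def fit_one_phase(
    t: np.ndarray, y: np.ndarray, no_offset: bool = True
) -> FrapFit:
    """Least-squares one-phase-association fit of a normalized recovery."""
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(t) < 4:
        raise FitError("need >= 4 post-bleach points")
    plateau0 = float(np.mean(y[-max(3, len(y) // 10):]))
    if plateau0 <= 1e-6:
        return FrapFit(
            y0=0.0, plateau=max(plateau0, 0.0), k=np.nan, mobile_fraction=0.0,
            rss=float(np.sum(y**2)), converged=False,
            message="flat curve: rate unidentifiable",
        )
    # K init from the time the curve first crosses half its final level
    half_idx = np.argmax(y >= plateau0 / 2)
    t_half0 = t[half_idx] if t[half_idx] > 0 else (t[1] if len(t) > 1 else 1.0)
    k0 = np.log(2) / t_half0

    try:
        if no_offset:
            model = lambda tt, plateau, k: plateau * (1 - np.exp(-k * tt))  # noqa: E731
            popt, _ = curve_fit(
                model, t, y, p0=[plateau0, k0],
                bounds=([0, 1e-12], [np.inf, np.inf]), maxfev=10000,
            )
            y0_fit, (plateau, k) = 0.0, popt
        else:
            model = lambda tt, y0, plateau, k: y0 + (plateau - y0) * (1 - np.exp(-k * tt))  # noqa: E731
            popt, _ = curve_fit(
                model, t, y, p0=[y[0], plateau0, k0],
                bounds=([-np.inf, -np.inf, 1e-12], [np.inf, np.inf, np.inf]),
                maxfev=10000,
            )
            y0_fit, plateau, k = popt
    except RuntimeError as exc:
        raise FitError(f"one-phase fit did not converge: {exc}") from exc
    resid = y - (y0_fit + (plateau - y0_fit) * (1 - np.exp(-k * t)))
    mobile = float(plateau)
    clipped = not 0 <= mobile <= 1
    return FrapFit(
        y0=float(y0_fit),
        plateau=float(plateau),
        k=float(k),
        mobile_fraction=float(np.clip(mobile, 0, 1)),
        rss=float(np.sum(resid**2)),
        converged=True,
        clipped=clipped,
    )


def fit_frap(traces: FrapTraces, no_offset: bool = True, with_d: bool = False) -> FrapFit:
    """Process raw traces and fit; optionally attach the Soumpasis D."""
    t, y = process_frap(traces)
    fit = fit_one_phase(t, y, no_offset=no_offset)
    if with_d and fit.converged:
        fit.d_um2_s = diffusion_coefficient(fit.t_half_s, traces.w_um)
    return fit


def diffusion_coefficient(t_half_s: float, w_um: float) -> float:
    """Soumpasis 2D diffusion coefficient, ``D = 0.224 w^2 / t_half``."""
    if t_half_s <= 0 or w_um <= 0:
        raise ValueError("t_half and spot radius must be positive")
    return SOUMPASIS_COEFF * w_um**2 / t_half_s


# ---------------------------------------------------------------------------
# Mass photometry

@dataclass
class Calibration:
    slope: float                 # kDa per contrast unit
    intercept: float             # kDa
    r_squared: float
    monotonic_warning: bool = False

    def apply(self, contrasts: np.ndarray) -> np.ndarray:
        return self.slope * np.asarray(contrasts, dtype=float) + self.intercept


def calibrate_masses(
    contrasts: np.ndarray, known_masses_kda: np.ndarray = None
) -> Calibration:
    """OLS contrast -> mass line through a standard ladder."""
    contrasts = np.asarray(contrasts, dtype=float)
    if known_masses_kda is None:
        known_masses_kda = np.asarray(BSA_LADDER_KDA[: len(contrasts)])
    masses = np.asarray(known_masses_kda, dtype=float)
    if len(np.unique(contrasts)) < 2:
        raise ValueError("need >= 2 standards with distinct contrasts")
    if len(contrasts) != len(masses):
        raise ValueError("contrast/mass length mismatch")
    res = linregress(contrasts, masses)
    order = np.argsort(contrasts)
    warn = bool(np.any(np.diff(masses[order]) <= 0))
    return Calibration(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        monotonic_warning=warn,
    )


@dataclass
class MassComponent:
    mean_kda: float
    sd_kda: float
    weight: float
    oligomer: int | None = None


@dataclass
class MassFit:
    components: list[MassComponent]
    n_components: int
    degenerate: bool = False
    calibration: Calibration | None = None

    def means(self) -> np.ndarray:
        return np.array([c.mean_kda for c in self.components])


_SD_FLOOR_KDA = 0.5


def fit_mass_distribution(
    sample: MassSample,
    n_components: int = 1,
    monomer_kda: float | None = None,
    seed: int = 0,
) -> MassFit:
    """Gaussian-mixture fit of the event-mass list by EM.

    Initialization is deterministic: component means start at evenly spaced
    quantiles of the sample, weights uniform, variances at the sample
    variance.  Components whose SD collapses to the floor trigger a refit
    with one component fewer (flagged ``degenerate``).  When a monomer mass
    is supplied each component is assigned the nearest oligomeric state.
    """
    x = np.asarray(sample.masses, dtype=float).reshape(-1, 1)
    if len(x) < 50:
        raise ValueError("need >= 50 events")
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    degenerate = False
    k = n_components
    while True:
        qs = np.quantile(x, (np.arange(k) + 0.5) / k).reshape(-1, 1)
        gm = GaussianMixture(
            n_components=k,
            covariance_type="full",
            means_init=qs,
            weights_init=np.full(k, 1 / k),
            precisions_init=np.full((k, 1, 1), 1 / max(x.var(), 1e-6)),
            max_iter=500,
            tol=1e-8,
            reg_covar=1e-6,
            random_state=seed,
        )
        gm.fit(x)
        sds = np.sqrt(gm.covariances_.ravel())
        if np.all(sds > _SD_FLOOR_KDA) or k == 1:
            break
        degenerate = True
        k -= 1
    order = np.argsort(gm.means_.ravel())
    comps = []
    for i in order:
        mean = float(gm.means_.ravel()[i])
        comp = MassComponent(
            mean_kda=mean,
            sd_kda=float(sds[i]),
            weight=float(gm.weights_[i]),
            oligomer=max(1, round(mean / monomer_kda)) if monomer_kda else None,
        )
        comps.append(comp)
    return MassFit(components=comps, n_components=k, degenerate=degenerate)


# ---------------------------------------------------------------------------
# Binding

@dataclass
class BindingFit:
    kd_um: float
    r0: float
    r_max: float
    rss: float
    converged: bool
    flagged: bool = False
    message: str = ""


def fit_binding(curve: BindingCurve) -> BindingFit:
    """Least-squares single-site fit; initialized at r0 = min, r_max = max,
    Kd = geometric mid-grid.  Kd at the grid bounds or a flat curve is
    flagged as unidentifiable."""
    conc = np.asarray(curve.concentration_um, dtype=float)
    r = np.asarray(curve.anisotropy, dtype=float)
    if len(conc) < 5:
        raise FitError("need >= 5 concentrations")
    span = r.max() - r.min()
    if span < 1e-12:
        return BindingFit(
            kd_um=np.nan, r0=float(r.mean()), r_max=float(r.mean()),
            rss=0.0, converged=False, flagged=True,
            message="flat curve: Kd unidentifiable",
        )
    pos = conc[conc > 0]
    kd0 = float(np.sqrt(pos.min() * pos.max())) if len(pos) else 1.0

    def model(L, r0, rmax, kd):
        return r0 + (rmax - r0) * L / (kd + L)

    try:
        popt, _ = curve_fit(
            model, conc, r, p0=[r.min(), r.max(), kd0],
            bounds=([-np.inf, -np.inf, 1e-12], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise FitError(f"binding fit did not converge: {exc}") from exc
    r0_fit, rmax_fit, kd = popt
    resid = r - model(conc, *popt)
    flagged = bool(
        kd <= pos.min() * 1.001 if len(pos) else True
    ) or bool(kd >= conc.max() * 0.999)
    return BindingFit(
        kd_um=float(kd),
        r0=float(r0_fit),
        r_max=float(rmax_fit),
        rss=float(np.sum(resid**2)),
        converged=True,
        flagged=flagged,
        message="Kd at grid bound" if flagged else "",
    )
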