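"""Effective camera spectral-response calibration from a colour target.

A physical camera photographs a reference colour board (>= 3 spectrally
distinct patches of known reflectance) head-on under a known illuminant in
open surroundings, so the normalised image value of each patch in each
channel equals the patch's camera-weighted reflectivity ``rho_o``.  Given
those measured values, the effective per-channel response ``C_lambda`` is
recovered by least squares: the response is expanded in a basis of smooth
non-negative Gaussian bumps spanning the channel's band, and the bump
amplitudes are fitted (bounded to [0, 1], with a second-difference
smoothness penalty and a hinge penalty keeping the reconstructed response
below 1) so that the predicted ``rho_o`` values match the measurements.

The same machinery supports a "no-target" mode: instead of measured images,
the user supplies desired patch values directly and obtains a simulated
camera response reproducing them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .spectra import Spectrum, WaveBand


@dataclass
class ColorTarget:
    """Named reflectance spectra of a calibration board's patches."""

    patches: dict[str, Spectrum]

    def __post_init__(self) -> None:
        if len(self.patches) < 3:
            raise ValueError("a colour target needs >= 3 patches")

    @property
    def names(self) -> list[str]:
        return list(self.patches)


@dataclass
class MeasuredPatchValues:
    """Observed normalised image values, one row per patch, one column per
    channel."""

    values: np.ndarray
    patch_names: list[str]
    channel_labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.patch_names), len(self.channel_labels)):
            raise ValueError("values shape must be (n_patches, n_channels)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("measured values must be finite")
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ValueError("measured values must lie in [0, 1]")


@dataclass
class ResponseModel:
    """Gaussian-bump expansion of a channel response.

    ``n_basis`` bumps are centred uniformly across each channel band with
    width sigma equal to the centre spacing; amplitudes are bounded to
    [0, 1] and regularised by ``smoothness_weight`` times the squared
    second difference.  ``bound_penalty`` weights the hinge keeping the
    reconstructed response at or below 1 where bumps overlap.
    """

    n_basis: int = 12
    smoothness_weight: float = 1e-3
    bound_penalty: float = 1e4

    def basis_matrix(self, band: WaveBand, grid: np.ndarray) -> np.ndarray:
        centers = np.linspace(band.lambda_min_nm, band.lambda_max_nm,
                              self.n_basis)
        sigma = centers[1] - centers[0] if self.n_basis > 1 else band.width_nm / 2
        return np.exp(-0.5 * ((grid[:, None] - centers[None, :]) / sigma) ** 2)

    def reconstruct(self, band: WaveBand, coeffs: np.ndarray,
                    step: float = 1.0) -> Spectrum:
        grid = np.arange(band.lambda_min_nm, band.lambda_max_nm + step / 2, step)
        c = self.basis_matrix(band, grid) @ coeffs
        return Spectrum(grid, np.clip(c, 0.0, 1.0))


def predict_patch_values(target: ColorTarget, S: Spectrum,
                         responses: dict[str, Spectrum | None],
                         bands: list[WaveBand]) -> MeasuredPatchValues:
    """Model-predicted patch values: the rho_o of each patch per channel."""
    from .spectra import band_camera_props

    zero = Spectrum.constant(0.0)
    vals = np.zeros((len(target.patches), len(bands)))
    for c, band in enumerate(bands):
        C = responses.get(band.label)
        for p, (name, rho) in enumerate(target.patches.items()):
            vals[p, c], _ = band_camera_props(rho, zero, C, S, band)
    return MeasuredPatchValues(vals, target.names, [b.label for b in bands])


@dataclass
class FitResult:
    responses: dict[str, Spectrum]
    coefficients: dict[str, np.ndarray]
    objective_history: dict[str, list[float]] = field(default_factory=dict)
    predicted: MeasuredPatchValues | None = None
    r2: float = np.nan


def fit_response(measured: MeasuredPatchValues, target: ColorTarget,
                 S: Spectrum, bands: list[WaveBand],
                 model: ResponseModel | None = None, seed: int = 0
                 ) -> FitResult:
    """Recover per-channel responses from measured patch values.

    Bounded least squares per channel (see :class:`ResponseModel`);
    deterministic under ``seed`` (which only perturbs the start point).
    Warns when the patch set cannot identify the basis (rank-deficient
    design); raises if the optimizer fails.
    """
    model = model or ResponseModel()
    if list(measured.patch_names) != target.names:
        raise ValueError("measured patch names do not match the target")
    rng = np.random.default_rng(seed)
    responses: dict[str, Spectrum] = {}
    coeffs: dict[str, np.ndarray] = {}
    history: dict[str, list[float]] = {}
    for c, band in enumerate(bands):
        grid = np.arange(band.lambda_min_nm, band.lambda_max_nm + 0.5, 1.0)
        Gb = model.basis_matrix(band, grid)                  # (L, K)
        s = S(grid)
        denom = np.trapezoid(s, grid)
        if denom <= 0:
            raise ValueError(f"source carries no energy in band {band.label!r}")
        # design: predicted value = sum_k a_k * int rho_p g_k S / int S
        R = np.stack([target.patches[n](grid) for n in target.patches])  # (P, L)
        weights = R * s[None, :]
        G = np.trapezoid(weights[:, :, None] * Gb[None, :, :],
                         grid, axis=1) / denom               # (P, K)
        if np.linalg.matrix_rank(G, tol=1e-10) < min(G.shape):
            warnings.warn(
                f"channel {band.label!r}: patch set does not identify the "
                "response basis (rank-deficient design); the fit is "
                "regularisation-dominated", stacklevel=2)
        m = measured.values[:, c]
        K = G.shape[1]
        D2 = np.diff(np.eye(K), n=2, axis=0)
        w = model.smoothness_weight
        mu = model.bound_penalty

        def objective(a):
            r = G @ a - m
            sm = D2 @ a
            over = np.maximum(Gb @ a - 1.0, 0.0)
            f = r @ r + w * (sm @ sm) + mu * (over @ over)
            g = (2 * G.T @ r + 2 * w * D2.T @ sm + 2 * mu * Gb.T @ over)
            return f, g

        x0 = np.full(K, 0.2) + 0.01 * rng.random(K)
        hist: list[float] = [float(objective(x0)[0])]
        res = minimize(objective, x0, jac=True, method="L-BFGS-B",
                       bounds=[(0.0, 1.0)] * K,
                       callback=lambda xk: hist.append(float(objective(xk)[0])),
                       options={"maxiter": 1000, "ftol": 1e-12, "gtol": 1e-10})
        # L-BFGS-B may stop on its internal rounding criterion after full
        # convergence; only a non-finite or worsened objective is a failure
        if not np.isfinite(res.fun) or res.fun > hist[0] + 1e-9:
            raise RuntimeError(
                f"response fit failed for channel {band.label!r}: {res.message}")
        coeffs[band.label] = res.x
        history[band.label] = hist
        responses[band.label] = model.reconstruct(band, res.x)
    predicted = predict_patch_values(target, S, responses, bands)
    r2 = calibration_r2(measured, predicted)
    return FitResult(responses, coeffs, history, predicted, r2)


def calibration_r2(measured: MeasuredPatchValues,
                   predicted: MeasuredPatchValues) -> float:
    """Coefficient of determination across all patch x channel values."""
    m = measured.values.ravel()
    p = predicted.values.ravel()
    if m.size != p.size:
        raise ValueError("measured and predicted sizes differ")
    if m.size < 2:
        raise ValueError("R^2 needs at least 2 values")
    ss_res = float(((m - p) ** 2).sum())
    ss_tot = float(((m - m.mean()) ** 2).sum())
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else 0.0
    return 1.0 - ss_res / ss_tot
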