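"""Bloch-Siegert phase model and the four B1+ measurement strategies.

An off-resonance sensitizing pulse at offset ``omega_rf`` (Hz, signed,
pulse-to-peak) shifts the phase of a spectral peak by

    phi_BS = pi * (gamma_b1_peak)^2 * B-tilde / omega_rf        [rad]

in the linear regime ``|omega_rf| >> gamma_b1``.  The strategies differ in
how many acquisitions and peaks contribute:

* ``A``        dual acquisition at +/-omega, one peak: Delta-phi = 2*phi_BS.
* ``Bprime``   dual acquisition pulse-on/pulse-off, one peak.
* ``Bdouble``  pulse-on/off with n peaks; per-peak B1^2 estimates are pooled
  by inverse-variance (maximum-likelihood) weights w_i = omega_i^-2.
* ``C``        one acquisition, n peaks; every peak pair (j, i) yields
  B1^2 = (phi_j - phi_i) / (pi * B-tilde * (1/omega_j - 1/omega_i)), pooled
  with weights (1/omega_j - 1/omega_i)^2.  Zeroth- and first-order spectral
  phase must already be corrected by the caller.

All phases are principal values in (-pi, pi]; unwrapping is explicit and
caller-driven.  Uncertainties propagate through the exact estimator
expressions by numerically differentiated error propagation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .pulses import ParameterError

GAMMA_31P = 17.235e6
"""Gyromagnetic ratio of phosphorus-31 in Hz/T."""

LINEARITY_FACTOR = 3.0  # warn when |omega_rf| < 3 * gamma_b1


@dataclass(frozen=True)
class BSPhaseModel:
    """Calibration of phase to B1: pulse shape integral and frequency offset.

    ``omega_rf`` is the signed offset (Hz) from the sensitizing pulse to the
    peak of interest; for Method A it is the magnitude of the symmetric
    offset.  ``b_tilde`` is the normalized squared integral of the unit-peak
    envelope (seconds).
    """

    b_tilde: float
    omega_rf: float
    gamma: float = GAMMA_31P

    def __post_init__(self) -> None:
        if not self.b_tilde > 0:
            raise ParameterError(f"b_tilde must be > 0, got {self.b_tilde}")
        if self.omega_rf == 0:
            raise ParameterError("omega_rf must be nonzero")


@dataclass(frozen=True)
class B1Estimate:
    """A gamma-B1 estimate with validity flagging.

    Invalid geometry (e.g. a negative phase difference under Method A) is
    encoded in ``valid``/``reason`` instead of raising, matching how excluded
    voxels are handled in map reconstruction.
    """

    gamma_b1: float
    sd: float | None = None
    valid: bool = True
    reason: str | None = None   # negative_phase_diff | crlb_exceeded | wrap_suspected


def bs_phase(gamma_b1_peak: float, model: BSPhaseModel) -> float:
    """Bloch-Siegert phase (radians) for a peak RF amplitude in Hz."""
    if abs(model.omega_rf) < LINEARITY_FACTOR * abs(gamma_b1_peak):
        warnings.warn(
            f"|omega_rf|={abs(model.omega_rf):.0f} Hz < "
            f"{LINEARITY_FACTOR:g} x gamma_b1={gamma_b1_peak:.0f} Hz; "
            "the linear phase model may be inaccurate",
            stacklevel=2,
        )
    return float(np.pi * gamma_b1_peak**2 * model.b_tilde / model.omega_rf)


def phase_difference(phi1, phi2):
    """Wrap-safe phase difference phi1 - phi2 in (-pi, pi].

    Computed through complex division, ``atan2`` of ``e^{i phi1}/e^{i phi2}``,
    so raw phases may carry any number of wraps.  Accepts arrays.
    """
    z = np.exp(1j * np.asarray(phi1)) / np.exp(1j * np.asarray(phi2))
    out = np.arctan2(np.imag(z), np.real(z))
    return float(out) if np.ndim(out) == 0 else out


def unwrap_phase_diff(delta_phi, k: int = 0):
    """Add ``k`` full turns to a wrapped phase difference.

    The wrap count is supplied per voxel or per ROI by the caller (manual
    unwrapping); ``k=1`` extends the measurable B1 range by sqrt(2).
    """
    return delta_phi + 2.0 * np.pi * k


# ---------------------------------------------------------------------------
# Vectorized B1^2 kernels (shared by the scalar API and the Monte Carlo loop)
# ---------------------------------------------------------------------------

def _b1sq_A(delta_phi, omega, b_tilde):
    return np.asarray(delta_phi) * omega / (2.0 * np.pi * b_tilde)


def _b1sq_Bprime(phi_on, phi_off, omega, b_tilde):
    return (np.asarray(phi_on) - np.asarray(phi_off)) * omega / (np.pi * b_tilde)


def _b1sq_Bdouble(phis_on, phis_off, omegas, b_tilde):
    """Pooled B1^2 over peaks; phase arrays may carry a leading draw axis."""
    omegas = np.asarray(omegas, dtype=float)
    per_peak = (np.asarray(phis_on) - np.asarray(phis_off)) * omegas / (np.pi * b_tilde)
    w = omegas**-2.0
    return np.sum(per_peak * w, axis=-1) / np.sum(w)


def _b1sq_C(phis, omegas, b_tilde):
    """Pooled B1^2 over all peak pairs (j < i)."""
    omegas = np.asarray(omegas, dtype=float)
    phis = np.asarray(phis)
    n = omegas.size
    jj, ii = np.triu_indices(n, k=1)
    dinv = 1.0 / omegas[jj] - 1.0 / omegas[ii]
    if np.any(dinv == 0):
        raise ParameterError("peak pair with equal offsets from the pulse")
    per_pair = (phis[..., jj] - phis[..., ii]) / (np.pi * b_tilde * dinv)
    w = dinv**2
    return np.sum(per_pair * w, axis=-1) / np.sum(w)


def _finalize(b1sq: float, sd: float | None = None) -> B1Estimate:
    if b1sq < 0:
        return B1Estimate(gamma_b1=np.nan, sd=sd, valid=False,
                          reason="negative_phase_diff")
    return B1Estimate(gamma_b1=float(np.sqrt(b1sq)), sd=sd)


def estimate_A(delta_phi: float, model: BSPhaseModel) -> B1Estimate:
    """Dual-acquisition +/- estimator: gamma_b1 = sqrt(dphi*omega/(2*pi*Bt)).

    ``delta_phi`` is the (+omega arm) minus (-omega arm) phase difference;
    ``model.omega_rf`` is the magnitude of the symmetric offset.  A negative
    phase difference (very low B1 or an uncorrected wrap) yields an invalid
    estimate.
    """
    return _finalize(_b1sq_A(delta_phi, abs(model.omega_rf), model.b_tilde))


def estimate_Bprime(phi_on: float, phi_off: float, model: BSPhaseModel) -> B1Estimate:
    """Single-peak on/off estimator: gamma_b1 = sqrt((on-off)*omega/(pi*Bt))."""
    return _finalize(_b1sq_Bprime(phi_on, phi_off, model.omega_rf, model.b_tilde))


def estimate_Bdouble(
    phis_on: Sequence[float],
    phis_off: Sequence[float],
    omegas: Sequence[float],
    model: BSPhaseModel,
) -> B1Estimate:
    """Multi-peak on/off estimator (maximum-likelihood pooled)."""
    phis_on = np.atleast_1d(np.asarray(phis_on, dtype=float))
    phis_off = np.atleast_1d(np.asarray(phis_off, dtype=float))
    omegas = np.atleast_1d(np.asarray(omegas, dtype=float))
    if not (phis_on.shape == phis_off.shape == omegas.shape):
        raise ParameterError("phis_on, phis_off and omegas must share a length")
    return _finalize(float(_b1sq_Bdouble(phis_on, phis_off, omegas, model.b_tilde)))


def estimate_C(
    phis: Sequence[float],
    omegas: Sequence[float],
    model: BSPhaseModel,
) -> B1Estimate:
    """Single-acquisition multi-peak estimator (pairwise pooled).

    Caller contract: ``phis`` are Bloch-Siegert phases only; zeroth- and
    first-order spectral phase must have been corrected beforehand.
    """
    phis = np.atleast_1d(np.asarray(phis, dtype=float))
    omegas = np.atleast_1d(np.asarray(omegas, dtype=float))
    if phis.shape != omegas.shape:
        raise ParameterError("phis and omegas must share a length")
    if phis.size < 2:
        raise ParameterError("Method C needs at least two peaks")
    return _finalize(float(_b1sq_C(phis, omegas, model.b_tilde)))


# ---------------------------------------------------------------------------
# Propagation of uncertainty
# ---------------------------------------------------------------------------

def propagate_error(
    strategy: str,
    phases: Sequence[float],
    crlbs: Sequence[float],
    model: BSPhaseModel,
    omegas: Sequence[float] | None = None,
) -> float:
    """Propagated SD of gamma-B1 (Hz) from per-phase uncertainties.

    The general first-order propagation ``Delta q = sqrt(sum (dq/dphi_i *
    Delta phi_i)^2)`` is applied to the exact estimator expression by central
    finite differences, so one code path serves all four strategies (the
    pairwise Method C expression has no compact closed form).

    ``phases`` per strategy: A -> (phi_plus, phi_minus); Bprime ->
    (phi_on, phi_off); Bdouble -> n on-phases then n off-phases; C -> n
    phases.  ``crlbs`` are the matching per-phase SDs in radians; pass 0 for
    a phase treated as exactly known.  A zero or invalid estimate yields
    ``inf`` (the relative uncertainty diverges as B1 -> 0).
    """
    phases = np.asarray(phases, dtype=float)
    crlbs = np.asarray(crlbs, dtype=float)
    if phases.shape != crlbs.shape:
        raise ParameterError("phases and crlbs must share a length")

    def value(p: np.ndarray) -> float:
        if strategy == "A":
            est = estimate_A(p[0] - p[1], model)
        elif strategy == "Bprime":
            est = estimate_Bprime(p[0], p[1], model)
        elif strategy == "Bdouble":
            n = p.size // 2
            est = estimate_Bdouble(p[:n], p[n:], omegas, model)
        elif strategy == "C":
            est = estimate_C(p, omegas, model)
        else:
            raise ParameterError(f"unknown strategy {strategy!r}")
        return est.gamma_b1 if est.valid else np.nan

    center = value(phases)
    if not np.isfinite(center) or center == 0.0:
        return float("inf")
    h = 1e-7  # rad; curvature of sqrt is mild at valid estimates
    var = 0.0
    for i in range(phases.size):
        if crlbs[i] == 0.0:
            continue
        dp = np.zeros_like(phases)
        dp[i] = h
        grad = (value(phases + dp) - value(phases - dp)) / (2.0 * h)
        var += (grad * crlbs[i]) ** 2
    return float(np.sqrt(var))


def propagate_error_A_closed_form(
    phi_plus: float, phi_minus: float,
    crlb_plus: float, crlb_minus: float,
    model: BSPhaseModel,
) -> float:
    """Closed-form SD for Method A, for cross-checking the numeric route:

    Delta gamma_b1 = sqrt(omega * (dphi+^2 + dphi-^2) /
                          (8 * pi * B-tilde * (phi+ - phi-)))
    """
    dphi = phi_plus - phi_minus
    if dphi <= 0:
        return float("inf")
    omega = abs(model.omega_rf)
    return float(np.sqrt(omega * (crlb_plus**2 + crlb_minus**2)
                         / (8.0 * np.pi * model.b_tilde * dphi)))


def dynamic_range(model: BSPhaseModel, max_phase: float) -> float:
    """Largest measurable gamma-B1 (Hz) before the phase difference wraps.

    ``max_phase`` is the usable phase-difference span (pi without unwrapping;
    2*pi after one manual unwrap).
    """
    return float(np.sqrt(max_phase * abs(model.omega_rf)
                         / (2.0 * np.pi * model.b_tilde)))


def flip_angle_from_b1(gamma_b1: float, tp: float) -> float:
    """Hard-pulse flip angle in degrees: theta = 360 * gamma_b1 * tp."""
    if tp <= 0:
        raise ParameterError(f"tp must be > 0, got {tp}")
    return 360.0 * gamma_b1 * tp


def b1_from_flip_angle(theta_deg: float, tp: float) -> float:
    """Inverse of :func:`flip_angle_from_b1` (Hz)."""
    if tp <= 0:
        raise ParameterError(f"tp must be > 0, got {tp}")
    return theta_deg / (360.0 * tp)


# ---------------------------------------------------------------------------
# Voxel maps and masking
# ---------------------------------------------------------------------------

EXCLUSION_CODES = {
    0: "none",
    1: "negative_phase_diff",
    2: "crlb_exceeded",
    3: "outside_geometry",
    4: "wrap_suspected",
}


@dataclass
class B1Map:
    """Per-voxel gamma-B1 map on a CSI grid with provenance.

    ``values`` are gamma-B1 in Hz; ``delta_phi_deg`` and ``crlb_phi_deg`` are
    the per-voxel phase differences and their CRLBs (degrees).  Exclusions
    are recorded as integer codes (:data:`EXCLUSION_CODES`) while the
    original values are retained.
    """

    values: np.ndarray
    delta_phi_deg: np.ndarray | None = None
    crlb_phi_deg: np.ndarray | None = None
    exclusion: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.exclusion is None:
            self.exclusion = np.zeros(self.values.shape, dtype=np.int8)

    @property
    def included(self) -> np.ndarray:
        return self.exclusion == 0

    def masked_values(self) -> np.ndarray:
        out = self.values.copy()
        out[~self.included] = np.nan
        return out


def mask_voxels(
    b1_map: B1Map,
    crlb_threshold_deg: float = 20.0,
    geometry_mask: np.ndarray | None = None,
) -> B1Map:
    """Flag low-quality voxels; values are retained with exclusion reasons.

    Voxels are excluded when the phase difference is negative (very low B1 or
    an uncorrected wrap), when the phase CRLB exceeds the threshold (low SNR;
    typical thresholds 20/10/15 degrees for phantom/limb/cardiac protocols),
    or when outside a supplied geometry mask.
    """
    if not crlb_threshold_deg > 0:
        raise ParameterError("crlb_threshold_deg must be > 0")
    excl = np.zeros(b1_map.values.shape, dtype=np.int8)
    if geometry_mask is not None:
        excl[~np.asarray(geometry_mask, dtype=bool)] = 3
    if b1_map.crlb_phi_deg is not None:
        excl[(excl == 0) & (b1_map.crlb_phi_deg > crlb_threshold_deg)] = 2
    if b1_map.delta_phi_deg is not None:
        excl[(excl == 0) & (b1_map.delta_phi_deg < 0)] = 1
    meta = dict(b1_map.meta)
    meta.update(
        crlb_threshold_deg=crlb_threshold_deg,
        n_excluded=int(np.count_nonzero(excl)),
        exclusion_counts={
            EXCLUSION_CODES[c]: int(np.count_nonzero(excl == c))
            for c in np.unique(excl)
        },
    )
    return B1Map(values=b1_map.values.copy(),
                 delta_phi_deg=b1_map.delta_phi_deg,
                 crlb_phi_deg=b1_map.crlb_phi_deg,
                 exclusion=excl, meta=meta)


def b1_map_from_phases(
    phi_plus_deg: np.ndarray,
    phi_minus_deg: np.ndarray,
    model: BSPhaseModel,
    crlb_phi_deg: np.ndarray | None = None,
    unwrap_k: int | np.ndarray = 0,
    method: str = "A",
) -> B1Map:
    """Build a Method A map from two per-voxel phase images (degrees)."""
    dphi = phase_difference(np.radians(phi_plus_deg), np.radians(phi_minus_deg))
    dphi = unwrap_phase_diff(dphi, unwrap_k)
    b1sq = _b1sq_A(dphi, abs(model.omega_rf), model.b_tilde)
    values = np.sqrt(np.clip(b1sq, 0.0, None))
    excl = np.where(b1sq < 0, np.int8(1), np.int8(0))
    return B1Map(
        values=values,
        delta_phi_deg=np.degrees(dphi),
        crlb_phi_deg=crlb_phi_deg,
        exclusion=excl,
        meta={"method": method, "omega_rf_hz": model.omega_rf,
              "b_tilde_s": model.b_tilde},
    )
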