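"""Nonparametric frequency-domain Granger causality and jackknife single-trial
correlation.

The cross-spectral density (CSD) of a site pair, estimated from Hann-tapered
zero-padded epochs, is factorized into a minimum-phase transfer function H and
an innovation covariance Sigma by Wilson's iterative spectral matrix
factorization (S = psi psi*, H = psi psi(0)^-1, Sigma = psi(0) psi(0)*).  The
Geweke frequency-domain measure then quantifies the directed influence at each
frequency.  Because GC is not defined per trial, its single-trial correlation
with reaction time uses the jackknife: the statistic is recomputed on every
leave-one-out subsample and correlated with the leave-one-out mean RT, which
for per-trial linear statistics is exactly the ordinary Pearson correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .spectral import SpectralFrame
from .phase_behavior import pearson_rows

__all__ = [
    "CrossSpectralMatrix",
    "SpectralFactorization",
    "GCSpectrum",
    "FactorizationError",
    "estimate_csd",
    "wilson_factorize",
    "granger_spectrum",
    "jackknife_correlation",
    "gc_rt_correlation",
    "var_spectral_matrix",
    "var_granger_spectrum",
]


class FactorizationError(RuntimeError):
    """Wilson iteration failed; carries the final relative update."""

    def __init__(self, msg, residual=np.nan):
        super().__init__(msg)
        self.residual = residual


@dataclass
class CrossSpectralMatrix:
    S: np.ndarray                 # (n_freq, k, k), Hermitian per frequency
    freqs: np.ndarray             # full 0..Nyquist grid, uniform spacing
    n_trials: int
    per_trial: np.ndarray | None = None   # (n_trials, n_freq, k, k) if kept

    def __post_init__(self):
        if not np.allclose(self.S, np.conj(np.swapaxes(self.S, -1, -2))):
            raise ValueError("CSD must be Hermitian at every frequency")
        if np.any(np.real(np.diagonal(self.S, axis1=-2, axis2=-1)) < -1e-12):
            raise ValueError("CSD diagonal must be nonnegative")


@dataclass
class SpectralFactorization:
    H: np.ndarray                 # (..., n_freq, k, k) transfer function
    Sigma: np.ndarray             # (..., k, k) innovation covariance
    iterations: int
    residual: float               # final relative psi update
    reconstruction_error: float   # max relative Frobenius error of H Sigma H*


@dataclass
class GCSpectrum:
    gc: np.ndarray                # (..., n_freq, 2): [a->b, b->a], nats
    freqs: np.ndarray
    aligned_band: str = ""

    def __post_init__(self):
        if np.any(self.gc < 0):
            raise ValueError("GC must be nonnegative (clip before constructing)")


# ---------------------------------------------------------------------------
# CSD estimation
# ---------------------------------------------------------------------------

def estimate_csd(frame: SpectralFrame, pair: tuple,
                 keep_trials: bool = False) -> CrossSpectralMatrix:
    """Trial-averaged cross-spectral density matrix of one site pair.

    S_ab(f) = mean_t coeff_a(f,t) conj(coeff_b(f,t)); Hermitian by
    construction.  The frame must carry the full 0..Nyquist grid (build it
    with ``fft_epochs(epochs, fmin=None)``) because the factorization needs
    the whole spectrum.
    """
    if frame.n_trials < 2:
        raise ValueError("CSD needs at least 2 trials")
    if frame.freqs[0] != 0.0:
        raise ValueError("CSD for factorization needs the full grid from 0 Hz"
                         " (use fft_epochs(..., fmin=None))")
    v = frame.coeff[list(pair), :, :]                  # (2, n_freq, n_trials)
    x = np.einsum("aft,bft->tfab", v, np.conj(v))
    S = x.mean(axis=0)
    S = 0.5 * (S + np.conj(np.swapaxes(S, -1, -2)))
    return CrossSpectralMatrix(S=S, freqs=frame.freqs.copy(),
                               n_trials=frame.n_trials,
                               per_trial=x if keep_trials else None)


# ---------------------------------------------------------------------------
# Wilson factorization
# ---------------------------------------------------------------------------

def _inv22(a: np.ndarray) -> np.ndarray:
    """Batched inverse of 2x2 matrices (faster than np.linalg.inv here)."""
    det = a[..., 0, 0] * a[..., 1, 1] - a[..., 0, 1] * a[..., 1, 0]
    out = np.empty_like(a)
    out[..., 0, 0] = a[..., 1, 1]
    out[..., 1, 1] = a[..., 0, 0]
    out[..., 0, 1] = -a[..., 0, 1]
    out[..., 1, 0] = -a[..., 1, 0]
    return out / det[..., None, None]


def _plus_operator(g: np.ndarray, n_onesided: int) -> np.ndarray:
    """Causal part of g: zero negative lags, halve (and upper-triangularize)
    the zero lag."""
    gam = np.fft.ifft(g, axis=-3)
    beta0 = 0.5 * gam[..., 0, :, :]
    k = beta0.shape[-1]
    beta0 = beta0 * np.triu(np.ones((k, k)))
    gam[..., 0, :, :] = beta0
    gam[..., n_onesided:, :, :] = 0.0
    return np.fft.fft(gam, axis=-3)


def wilson_factorize(csd, tol: float = 1e-12, max_iter: int = 1000,
                     strict: bool = True) -> SpectralFactorization:
    """Wilson's iterative minimum-phase spectral matrix factorization.

    Accepts a CrossSpectralMatrix or a raw array (..., n_freq, k, k) on the
    one-sided 0..Nyquist grid; leading axes are batched (used for jackknife
    replications).  Diagonal loading eps = 1e-8 trace(S)/k is applied where
    the smallest eigenvalue is below eps.  Iterates psi <- psi [psi^-1 S
    psi^-* + I]_+ until the maximal relative update falls below ``tol``.
    """
    S = csd.S if isinstance(csd, CrossSpectralMatrix) else np.asarray(csd)
    S = 0.5 * (S + np.conj(np.swapaxes(S, -1, -2)))
    nf = S.shape[-3]
    k = S.shape[-1]

    eig = np.linalg.eigvalsh(S)
    trace = np.real(np.trace(S, axis1=-2, axis2=-1))
    eps = 1e-8 * trace.mean() / k
    if eig.min() < eps:
        S = S + eps * np.eye(k)

    # two-sided spectrum: S(-f) = conj(S(f))
    S2 = np.concatenate([S, np.conj(S[..., 1:-1, :, :][..., ::-1, :, :])],
                        axis=-3)

    gam0 = np.real(np.fft.ifft(S2, axis=-3)[..., 0, :, :])
    try:
        psi0 = np.swapaxes(np.linalg.cholesky(gam0), -1, -2)  # upper triangular
    except np.linalg.LinAlgError as e:
        raise FactorizationError(f"initial covariance not positive definite: {e}")
    psi = np.broadcast_to(psi0[..., None, :, :], S2.shape).astype(complex).copy()

    inv = _inv22 if k == 2 else np.linalg.inv
    eye = np.eye(k)
    residual = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        invpsi = inv(psi)
        g = invpsi @ S2 @ np.conj(np.swapaxes(invpsi, -1, -2)) + eye
        gp = _plus_operator(g, nf)
        psi_new = psi @ gp
        num = np.abs(psi_new - psi).max()
        den = np.abs(psi).max()
        residual = num / den if den > 0 else num
        psi = psi_new
        if residual < tol:
            break
    if residual >= tol and strict:
        raise FactorizationError(
            f"Wilson factorization did not converge in {max_iter} iterations "
            f"(relative update {residual:.3e})", residual)

    A0 = np.real(np.fft.ifft(psi, axis=-3)[..., 0, :, :])
    if np.any(np.abs(np.linalg.det(A0)) < 1e-300):
        raise FactorizationError("singular psi(0): noise covariance undefined")
    H = psi[..., :nf, :, :] @ inv(A0)[..., None, :, :]
    Sigma = A0 @ np.swapaxes(A0, -1, -2)

    recon = H @ Sigma[..., None, :, :] @ np.conj(np.swapaxes(H, -1, -2))
    num = np.linalg.norm(recon - S, axis=(-2, -1))
    den = np.linalg.norm(S, axis=(-2, -1))
    rec_err = float((num / np.maximum(den, 1e-300)).max())
    return SpectralFactorization(H=H, Sigma=Sigma, iterations=it,
                                 residual=float(residual),
                                 reconstruction_error=rec_err)


# ---------------------------------------------------------------------------
# Geweke GC
# ---------------------------------------------------------------------------

def _geweke(Saa, H_target, H_self, Sigma, i, j):
    """GC from channel j onto channel i given row i of H and Sigma."""
    s_ii = Sigma[..., i, i][..., None]
    s_jj = Sigma[..., j, j][..., None]
    s_ij = Sigma[..., i, j][..., None]
    Ht = H_target + (s_ij / s_ii) * H_self
    noise = s_jj - s_ij**2 / s_ii
    den = Saa - noise * np.abs(Ht) ** 2
    bad = den <= 0
    if np.any(bad):
        warnings.warn("non-positive GC log argument clipped")
        den = np.where(bad, Saa * 1e-15, den)
    return np.log(Saa / den)


def granger_spectrum(fact: SpectralFactorization, csd) -> GCSpectrum:
    """Geweke frequency-domain GC in both directions from a bivariate
    factorization.

    gc[..., 0] is the influence of the first channel onto the second (a->b),
    gc[..., 1] the reverse.  Numerically negative values beyond -1e-10 trigger
    a warning; all negatives are clipped to 0.
    """
    S = csd.S if isinstance(csd, CrossSpectralMatrix) else np.asarray(csd)
    H, Sigma = fact.H, fact.Sigma
    Saa = np.real(S[..., 0, 0])
    Sbb = np.real(S[..., 1, 1])
    gc_b_to_a = _geweke(Saa, H[..., 0, 1], H[..., 0, 0], Sigma, 0, 1)
    gc_a_to_b = _geweke(Sbb, H[..., 1, 0], H[..., 1, 1], Sigma, 1, 0)
    gc = np.stack([gc_a_to_b, gc_b_to_a], axis=-1)
    if np.any(gc < -1e-10):
        warnings.warn(f"GC numerically negative (min {gc.min():.3e}); clipped to 0")
    gc = np.clip(gc, 0.0, None)
    freqs = csd.freqs if isinstance(csd, CrossSpectralMatrix) \
        else np.arange(gc.shape[-2], dtype=float)
    return GCSpectrum(gc=gc, freqs=freqs)


# ---------------------------------------------------------------------------
# VAR oracle helpers (closed-form spectra for validation)
# ---------------------------------------------------------------------------

def var_spectral_matrix(A: np.ndarray, Sigma: np.ndarray,
                        freqs: np.ndarray, sample_rate: float) -> np.ndarray:
    """Analytic CSD of a VAR(p): S(f) = H(f) Sigma H(f)* with
    H(f) = (I - sum_m A_m e^{-i 2 pi f m / fs})^-1."""
    k = A.shape[-1]
    S = np.empty((len(freqs), k, k), dtype=complex)
    for fi, f in enumerate(freqs):
        Af = np.eye(k, dtype=complex)
        for m in range(A.shape[0]):
            Af -= A[m] * np.exp(-2j * np.pi * f * (m + 1) / sample_rate)
        H = np.linalg.inv(Af)
        S[fi] = H @ Sigma @ np.conj(H.T)
    return S


def var_granger_spectrum(A: np.ndarray, Sigma: np.ndarray, freqs: np.ndarray,
                         sample_rate: float) -> GCSpectrum:
    """Parametric GC from the true VAR coefficients (independent oracle)."""
    k = A.shape[-1]
    S = var_spectral_matrix(A, Sigma, freqs, sample_rate)
    H = np.empty_like(S)
    for fi, f in enumerate(freqs):
        Af = np.eye(k, dtype=complex)
        for m in range(A.shape[0]):
            Af -= A[m] * np.exp(-2j * np.pi * f * (m + 1) / sample_rate)
        H[fi] = np.linalg.inv(Af)
    fact = SpectralFactorization(H=H, Sigma=Sigma.astype(float), iterations=0,
                                 residual=0.0, reconstruction_error=0.0)
    csd = CrossSpectralMatrix(S=0.5 * (S + np.conj(np.swapaxes(S, -1, -2))),
                              freqs=freqs, n_trials=2)
    return granger_spectrum(fact, csd)


# ---------------------------------------------------------------------------
# jackknife correlation
# ---------------------------------------------------------------------------

def jackknife_correlation(per_trial_or_statistic, rt: np.ndarray) -> np.ndarray:
    """Correlation between leave-one-out statistics and leave-one-out mean RT.

    First argument: either a per-trial array (n_trials, ...) whose statistic
    is the trial mean (fast affine path), or a callable mapping a trial-index
    array to the statistic of that subsample.  For per-trial linear statistics
    the result equals the ordinary Pearson correlation exactly.  Constant RT
    yields NaN (undefined, reported missing).
    """
    rt = np.asarray(rt, dtype=float)
    n = len(rt)
    if n < 3:
        raise ValueError("jackknife needs at least 3 trials")
    if callable(per_trial_or_statistic):
        vals = []
        idx = np.arange(n)
        for i in range(n):
            try:
                vals.append(np.asarray(per_trial_or_statistic(np.delete(idx, i)),
                                       dtype=float))
            except Exception as e:
                raise RuntimeError(f"statistic failed on leave-one-out "
                                   f"replication {i}") from e
        vals = np.stack(vals)
    else:
        x = np.asarray(per_trial_or_statistic, dtype=float)
        if x.shape[0] != n:
            raise ValueError("per-trial values and rt must share the trial axis")
        vals = (x.sum(axis=0) - x) / (n - 1)
    rt_loo = (rt.sum() - rt) / (n - 1)
    flat = vals.reshape(n, -1)
    r = pearson_rows(flat.T, rt_loo)
    return r.reshape(vals.shape[1:]) if vals.ndim > 1 else float(r[0])


def gc_rt_correlation(frame: SpectralFrame, pairs: list, rt: np.ndarray,
                      tol: float = 1e-9, max_iter: int = 100,
                      strict: bool = False) -> dict:
    """Jackknife correlation between GC spectra and RT, per direction.

    For every site pair, the leave-one-out CSDs (affine updates of the
    trial-averaged CSD) are factorized in one batch, the Geweke spectra are
    computed per replication, and each frequency/direction is correlated with
    the leave-one-out mean RT.  Spectra are then averaged over site pairs.
    Directions: index 0 = first site of the pair onto the second, 1 = reverse.
    """
    rt = np.asarray(rt, dtype=float)
    per_pair = []
    for pair in pairs:
        csd = estimate_csd(frame, pair, keep_trials=True)
        n = csd.n_trials
        if n != len(rt):
            raise ValueError("rt must match the frame's trials")
        S_loo = (n * csd.S[None] - csd.per_trial) / (n - 1)
        fact = wilson_factorize(S_loo, tol=tol, max_iter=max_iter,
                                strict=strict)
        gc = granger_spectrum(fact, S_loo).gc          # (n, n_freq, 2)
        rt_loo = (rt.sum() - rt) / (n - 1)
        r = pearson_rows(np.moveaxis(gc, 0, -1), rt_loo)   # (n_freq, 2)
        per_pair.append(r)
    per_pair = np.stack(per_pair)
    return {"freqs": frame.freqs.copy(),
            "per_pair": per_pair,
            "mean": np.nanmean(per_pair, axis=0)}
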