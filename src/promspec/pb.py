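"""Harmonic lattice model of promoter DNA and eigenvector localization.

Each nucleotide n carries one displacement coordinate y_n (base-pair
stretching).  The potential energy combines an on-site Morse well, whose
depth/width depend on whether the site is weak (A/T) or strong (C/G), with
a nonlinear stacking spring between neighbours:

    V(y) = sum_n D_n (exp(-a_n y_n) - 1)^2
         + sum_{n>=2} k/2 * (1 + rho * exp(-alpha (y_n + y_{n-1})))
                        * (y_n - y_{n-1})^2

The ground state is y = 0.  In the harmonic (small-oscillation) regime the
chain is fully characterised by the Hessian of V at the minimum, a
symmetric tridiagonal matrix with free-boundary ends:

    diagonal  : (#neighbours) * k (1 + rho) + 2 D_n a_n^2
    off-diag  : -k (1 + rho)

Note the stacking decay ``alpha`` multiplies terms that vanish at y = 0,
so it never enters the Hessian; it is kept for the full-potential oracle.

Per-eigenvector localization indicators (for a unit-norm vector v):

    participation number  P     = 1 / sum_n v_n^4
    center of mass        n_cm  = sum_n n v_n^2
    start / end sites     s, e  : smallest n with sum_{j<=n} v_j^2 > eps,
                                  largest n with sum_{j>=n} v_j^2 > eps
    extension             ext   = span of components with |v_n| > delta
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .seqio import BinarySequence


@dataclass(frozen=True)
class PBParameters:
    """Lattice parameters (eV / angstrom units).

    Defaults follow the Campa-Giansanti parameter set; the strong-site
    Morse depth is conventionally 1.5x the weak one (warned, not
    enforced).
    """

    k: float = 0.025        # stacking stiffness, eV/A^2
    rho: float = 2.0        # stacking anharmonicity amplitude
    alpha: float = 0.35     # stacking decay, 1/A (absent from the Hessian)
    D_W: float = 0.05       # Morse depth, weak sites, eV
    D_S: float = 0.075      # Morse depth, strong sites, eV
    a_W: float = 4.2        # Morse width, weak sites, 1/A
    a_S: float = 6.9        # Morse width, strong sites, 1/A

    def __post_init__(self) -> None:
        for name in ("k", "rho", "alpha", "D_W", "D_S", "a_W", "a_S"):
            if getattr(self, name) <= 0:
                raise ValueError(f"parameter {name} must be positive")
        if not np.isclose(self.D_S, 1.5 * self.D_W):
            warnings.warn(
                f"D_S = {self.D_S} is not 1.5 * D_W = {1.5 * self.D_W}",
                stacklevel=2,
            )

    @property
    def coupling(self) -> float:
        """Harmonic stacking constant k * (1 + rho)."""
        return self.k * (1.0 + self.rho)

    def onsite(self, strong: np.ndarray) -> np.ndarray:
        """Per-site curvature 2 D a^2 of the Morse well at y = 0."""
        kW = 2.0 * self.D_W * self.a_W**2
        kS = 2.0 * self.D_S * self.a_S**2
        return np.where(strong, kS, kW)


def potential_energy(y: np.ndarray, binary: BinarySequence, params: PBParameters) -> float:
    """Full (anharmonic) potential energy of a chain configuration.

    Used as the independent oracle for the Hessian via finite differences.
    """
    y = np.asarray(y, dtype=float)
    strong = binary.as_array()
    if y.shape != (len(binary),):
        raise ValueError("configuration length does not match sequence")
    D = np.where(strong, params.D_S, params.D_W)
    a = np.where(strong, params.a_S, params.a_W)
    morse = np.sum(D * (np.exp(-a * y) - 1.0) ** 2)
    dy = y[1:] - y[:-1]
    stack = np.sum(
        0.5 * params.k * (1.0 + params.rho * np.exp(-params.alpha * (y[1:] + y[:-1]))) * dy**2
    )
    return float(morse + stack)


@dataclass(frozen=True)
class TridiagonalHessian:
    """Hessian of the chain potential at y = 0 (free boundaries)."""

    diag: np.ndarray
    offdiag: np.ndarray  # length L-1, constant -k(1+rho)

    @property
    def L(self) -> int:
        return len(self.diag)

    def toarray(self) -> np.ndarray:
        return (
            np.diag(self.diag)
            + np.diag(self.offdiag, 1)
            + np.diag(self.offdiag, -1)
        )

    @property
    def trace(self) -> float:
        return float(self.diag.sum())


def build_hessian(binary: BinarySequence, params: PBParameters | None = None) -> TridiagonalHessian:
    """Exact second derivatives of the chain potential at the minimum."""
    params = params or PBParameters()
    L = len(binary)
    if L < 2:
        raise ValueError("chain needs at least 2 sites")
    c = params.coupling
    strong = binary.as_array()
    diag = params.onsite(strong).astype(float)
    diag[0] += c
    diag[-1] += c
    diag[1:-1] += 2.0 * c
    offdiag = np.full(L - 1, -c)
    return TridiagonalHessian(diag=diag, offdiag=offdiag)


@dataclass
class HessianSpectrum:
    """Full spectrum of one promoter chain, ascending eigenvalues.

    Eigenvectors are orthonormal columns with the sign fixed so the
    largest-magnitude component is positive.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray

    @property
    def L(self) -> int:
        return len(self.eigenvalues)

    def mode(self, m: int) -> np.ndarray:
        return self.eigenvectors[:, m]


def diagonalize(H: TridiagonalHessian) -> HessianSpectrum:
    """Solve the spectral problem for the tridiagonal Hessian."""
    try:
        vals, vecs = scipy.linalg.eigh_tridiagonal(H.diag, H.offdiag)
    except scipy.linalg.LinAlgError as exc:  # pragma: no cover
        raise RuntimeError(f"eigendecomposition failed: {exc}") from exc
    # deterministic sign: largest-|.| component positive
    flips = np.sign(vecs[np.abs(vecs).argmax(axis=0), np.arange(vecs.shape[1])])
    flips[flips == 0] = 1.0
    vecs = vecs * flips[None, :]
    return HessianSpectrum(eigenvalues=vals, eigenvectors=vecs)


def uniform_chain_eigenvalues(L: int, strong: bool, params: PBParameters | None = None) -> np.ndarray:
    """Closed-form spectrum of a homogeneous free-boundary chain.

    lambda_m = 2 D a^2 + 2 k (1 + rho) (1 - cos(m pi / L)), m = 0..L-1.
    """
    params = params or PBParameters()
    D, a = (params.D_S, params.a_S) if strong else (params.D_W, params.a_W)
    m = np.arange(L)
    return 2.0 * D * a**2 + 2.0 * params.coupling * (1.0 - np.cos(m * np.pi / L))


@dataclass(frozen=True)
class EigenvectorIndicators:
    """Localization summary of one unit-norm eigenvector."""

    P: float       # participation number, 1..L
    n_cm: float    # center of mass, 1..L
    s: int         # start site (1-based)
    e: int         # end site (1-based)
    ext: int       # extension in sites

    @property
    def span(self) -> int:
        return self.e - self.s + 1


def indicators(
    v: np.ndarray,
    eps: float = 0.01,
    delta: float = 1e-4,
    extension_def: str = "threshold",
) -> EigenvectorIndicators:
    """Localization indicators of a unit-norm eigenvector.

    ``eps`` is the cumulative-mass tail threshold defining the start/end
    sites; ``delta`` is the per-component threshold defining the
    extension (it removes the ambiguity of very small components).
    ``extension_def='rms'`` swaps the threshold-based extension for
    ``1 + 2 * rms spread`` of the component weights around the center of
    mass.
    """
    v = np.asarray(v, dtype=float)
    w = v**2
    total = w.sum()
    if abs(np.sqrt(total) - 1.0) > 1e-6:
        raise ValueError("eigenvector must be normalized to unit norm")
    L = len(v)
    n = np.arange(1, L + 1)
    P = 1.0 / np.sum(w**2)
    n_cm = float(np.sum(n * w))
    cum = np.cumsum(w)
    s = int(np.argmax(cum > eps)) + 1
    rcum = np.cumsum(w[::-1])[::-1]
    e = L - int(np.argmax(rcum[::-1] > eps))
    if extension_def == "rms":
        spread = np.sqrt(np.sum((n - n_cm) ** 2 * w))
        ext = int(round(1.0 + 2.0 * spread))
    elif extension_def == "threshold":
        big = np.flatnonzero(np.abs(v) > delta)
        ext = int(big[-1] - big[0] + 1) if big.size else 0
    else:
        raise ValueError(f"unknown extension definition {extension_def!r}")
    return EigenvectorIndicators(P=float(P), n_cm=n_cm, s=s, e=e, ext=ext)


def spectrum_indicators(
    spectrum: HessianSpectrum,
    eps: float = 0.01,
    delta: float = 1e-4,
    extension_def: str = "threshold",
) -> list[EigenvectorIndicators]:
    """Indicators for every mode of a spectrum (vectorised)."""
    V = spectrum.eigenvectors
    W = V**2
    L = V.shape[0]
    n = np.arange(1, L + 1)
    P = 1.0 / np.sum(W**2, axis=0)
    n_cm = n @ W
    cum = np.cumsum(W, axis=0)
    s = np.argmax(cum > eps, axis=0) + 1
    rcum = np.cumsum(W[::-1], axis=0)[::-1]
    e = L - np.argmax(rcum[::-1] > eps, axis=0)
    if extension_def == "rms":
        spread = np.sqrt(np.sum((n[:, None] - n_cm[None, :]) ** 2 * W, axis=0))
        exts = np.round(1.0 + 2.0 * spread).astype(int)
    elif extension_def == "threshold":
        absV = np.abs(V) > delta
        exts = np.zeros(V.shape[1], dtype=int)
        for m in range(V.shape[1]):
            big = np.flatnonzero(absV[:, m])
            exts[m] = big[-1] - big[0] + 1 if big.size else 0
    else:
        raise ValueError(f"unknown extension definition {extension_def!r}")
    return [
        EigenvectorIndicators(
            P=float(P[m]), n_cm=float(n_cm[m]), s=int(s[m]), e=int(e[m]), ext=int(exts[m])
        )
        for m in range(V.shape[1])
    ]
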