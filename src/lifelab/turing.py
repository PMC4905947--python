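"""Linear stability of reaction-diffusion dynamics on a ring of cells.

The model is the discrete cellular case: N identical cells in a ring,
each holding m morphogen concentrations, with linearized reaction
kinetics given by an m-by-m Jacobian J (entry (i, j) is the sensitivity
of morphogen i's production rate to morphogen j) and nearest-neighbor
exchange at per-morphogen rates mu_i. Perturbations decompose into ring
modes: the mode with wavenumber k evolves under

    M_k = J - 4 sin^2(pi k / N) * diag(mu),

since the discrete Laplacian on the ring has eigenvalues
-4 sin^2(pi k / N). Each mode is classified on two axes:

* temporal: *stationary* (dominant eigenvalue real — the perturbation
  grows or decays in place) vs *oscillatory* (complex — it waxes and
  wanes or travels);
* wavelength: *extremely long* (k near 0, the whole ring moves
  together), *extremely short* (k near N/2, neighboring cells
  anti-phase) or *finite* — the regime that produces stable standing
  patterns with a preferred number of waves around the ring.

A growing stationary finite-wavelength mode is the classic Turing
instability; a growing oscillatory one at finite wavelength requires at
least three interacting morphogens, a claim this module probes
empirically by random sampling rather than proof. The typology parallels
the cellular-automaton taxonomy: stationary instabilities freeze into
still-life-like patterns, oscillatory ones blink.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

TEMPORAL_CLASSES = ("stationary", "oscillatory")
STABILITIES = ("growing", "decaying", "marginal")
WAVELENGTH_CLASSES = ("extremely_long", "extremely_short", "finite")

#: Wavelength-class boundaries as fractions of N. Turing's categories are
#: qualitative; these numeric cutoffs are configurable.
LONG_FRACTION = 0.05
SHORT_FRACTION = 0.45

DEFAULT_TOL = 1e-9


@dataclass(frozen=True)
class RingModel:
    """An m-morphogen reaction-diffusion system on an N-cell ring."""

    n_cells: int
    jacobian: np.ndarray
    diffusion: np.ndarray

    def __post_init__(self) -> None:
        J = np.asarray(self.jacobian, dtype=float)
        D = np.asarray(self.diffusion, dtype=float)
        if J.ndim != 2 or J.shape[0] != J.shape[1]:
            raise ValueError(f"jacobian must be square, got shape {J.shape}")
        if D.shape != (J.shape[0],):
            raise ValueError("diffusion must have one rate per morphogen")
        if np.any(D < 0):
            raise ValueError("diffusion rates must be nonnegative")
        if self.n_cells < 3:
            raise ValueError("a ring needs at least 3 cells")
        object.__setattr__(self, "jacobian", J)
        object.__setattr__(self, "diffusion", D)

    @property
    def n_morphogens(self) -> int:
        return self.jacobian.shape[0]


@dataclass(frozen=True)
class ModeResult:
    """Classification of one ring mode."""

    k: int
    eigenvalues: Tuple[complex, ...]
    max_real_part: float
    temporal_class: str
    stability: str
    wavelength_class: str


@dataclass(frozen=True)
class SystemResult:
    """Full per-wavenumber table plus the dominant mode."""

    dominant: ModeResult
    modes: Tuple[ModeResult, ...]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for m in self.modes:
            lam = max(m.eigenvalues, key=lambda z: (z.real, abs(z.imag)))
            rows.append(
                {
                    "k": m.k,
                    "max_real_part": m.max_real_part,
                    "imag_part": abs(lam.imag),
                    "temporal_class": m.temporal_class,
                    "stability": m.stability,
                    "wavelength_class": m.wavelength_class,
                    "dominant": m.k == self.dominant.k,
                }
            )
        return pd.DataFrame(rows)


def _damping(n_cells: int, k: int) -> float:
    # min(k, N-k) keeps the k <-> N-k symmetry exact in floating point
    keff = min(k, n_cells - k)
    return 4.0 * np.sin(np.pi * keff / n_cells) ** 2


def mode_matrix(model: RingModel, k: int) -> np.ndarray:
    """The m-by-m matrix governing ring mode ``k``: J - 4 sin^2(pi k/N) diag(mu)."""
    if not (0 <= k < model.n_cells):
        raise ValueError(f"wavenumber k must be in 0..{model.n_cells - 1}, got {k}")
    return model.jacobian - _damping(model.n_cells, k) * np.diag(model.diffusion)


def _wavelength_class(
    k: int, n_cells: int, long_frac: float, short_frac: float
) -> str:
    frac = min(k, n_cells - k) / n_cells
    if frac <= long_frac:
        return "extremely_long"
    if frac >= short_frac:
        return "extremely_short"
    return "finite"


def classify_mode(
    model: RingModel,
    k: int,
    growth_tol: float = DEFAULT_TOL,
    imag_tol: float = DEFAULT_TOL,
    long_frac: float = LONG_FRACTION,
    short_frac: float = SHORT_FRACTION,
) -> ModeResult:
    """Eigen-classify ring mode ``k``.

    Tolerances are relative to the Jacobian's norm: an eigenvalue's real
    part within ``growth_tol * (1 + ||J||)`` of zero is marginal, and its
    imaginary part must exceed ``imag_tol * (1 + ||J||)`` for the mode to
    count as oscillatory.
    """
    if growth_tol <= 0 or imag_tol <= 0:
        raise ValueError("tolerances must be positive")
    eig = np.linalg.eigvals(mode_matrix(model, k))
    scale = 1.0 + np.linalg.norm(model.jacobian)
    gtol = growth_tol * scale
    itol = imag_tol * scale
    # Dominant eigenvalue: max real part; among ties prefer larger |imag|
    dom = max(eig, key=lambda z: (z.real, abs(z.imag)))
    max_re = float(dom.real)
    if max_re > gtol:
        stability = "growing"
    elif max_re < -gtol:
        stability = "decaying"
    else:
        stability = "marginal"
    temporal = "oscillatory" if abs(dom.imag) > itol else "stationary"
    return ModeResult(
        k=k,
        eigenvalues=tuple(complex(z) for z in eig),
        max_real_part=max_re,
        temporal_class=temporal,
        stability=stability,
        wavelength_class=_wavelength_class(k, model.n_cells, long_frac, short_frac),
    )


def classify_system(
    model: RingModel,
    growth_tol: float = DEFAULT_TOL,
    imag_tol: float = DEFAULT_TOL,
    long_frac: float = LONG_FRACTION,
    short_frac: float = SHORT_FRACTION,
) -> SystemResult:
    """Classify every ring mode and single out the dominant one.

    The dominant mode maximizes the largest eigenvalue real part over
    k = 0..N-1; ties go to the smallest k. Its class is what the
    homogeneous state's fate maps onto: a growing stationary dominant
    mode freezes into pattern, a growing oscillatory one into rhythm.
    """
    modes = tuple(
        classify_mode(model, k, growth_tol, imag_tol, long_frac, short_frac)
        for k in range(model.n_cells)
    )
    dominant = modes[int(np.argmax([m.max_real_part for m in modes]))]
    return SystemResult(dominant=dominant, modes=modes)


@dataclass(frozen=True)
class ScanResult:
    """Outcome of a random-model search."""

    count: int
    n_samples: int
    examples: Tuple[RingModel, ...]

    @property
    def fraction(self) -> float:
        return self.count / self.n_samples


def scan_for_oscillatory_finite(
    m: int,
    n_samples: int,
    seed: int,
    n_cells: int = 20,
    growth_tol: float = DEFAULT_TOL,
    imag_tol: float = DEFAULT_TOL,
    long_frac: float = LONG_FRACTION,
    short_frac: float = SHORT_FRACTION,
    max_examples: int = 5,
) -> ScanResult:
    """Count random models whose *dominant* instability is oscillatory at finite wavelength.

    Samples Jacobians with entries uniform in [-1, 1] and diffusion
    rates uniform in [0, 1]; a hit is a model whose dominant mode is
    growing, oscillatory and of finite wavelength class. For m = 2 the
    count is zero for a structural reason: complex eigenvalues of a
    2-by-2 real matrix share the real part trace/2, and diffusion only
    lowers the trace as k grows, so an oscillatory pair can never
    dominate at finite k — wave instabilities need a third morphogen.
    The scan tests this empirically, and for m >= 3 doubles as a fixture
    finder (up to ``max_examples`` hit models are returned).
    """
    if m < 1:
        raise ValueError("need at least one morphogen")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    jacobians = rng.uniform(-1.0, 1.0, size=(n_samples, m, m))
    diffusions = rng.uniform(0.0, 1.0, size=(n_samples, m))
    # By the k <-> N-k symmetry only k = 0..floor(N/2) need eigenvalues,
    # and the smallest-k tie-break can never select a mirrored k.
    ks = np.arange(n_cells // 2 + 1)
    damp = 4.0 * np.sin(np.pi * ks / n_cells) ** 2  # (K,)
    eye = np.eye(m)
    # (n, K, m, m): J broadcast minus per-k damping of diag(D)
    mats = (
        jacobians[:, None, :, :]
        - damp[None, :, None, None] * (eye[None, None, :, :] * diffusions[:, None, None, :])
    )
    eig = np.linalg.eigvals(mats.reshape(-1, m, m)).reshape(n_samples, len(ks), m)
    max_re = eig.real.max(axis=2)  # (n, K)
    k_dom = max_re.argmax(axis=1)  # first max -> smallest k
    scale = 1.0 + np.linalg.norm(jacobians, axis=(1, 2))
    count = 0
    examples: List[RingModel] = []
    for i in range(n_samples):
        kd = int(k_dom[i])
        frac = kd / n_cells  # kd <= N/2 so this is already min(k, N-k)/N
        if not (long_frac < frac < short_frac):
            continue
        row = eig[i, kd]
        dom = row[np.lexsort((np.abs(row.imag), row.real))[-1]]
        gtol = growth_tol * scale[i]
        itol = imag_tol * scale[i]
        if dom.real > gtol and abs(dom.imag) > itol:
            count += 1
            if len(examples) < max_examples:
                examples.append(
                    RingModel(n_cells, jacobians[i].copy(), diffusions[i].copy())
                )
    return ScanResult(count=count, n_samples=n_samples, examples=tuple(examples))
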