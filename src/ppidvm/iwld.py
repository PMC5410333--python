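"""Improved Weber Local Descriptor (IWLD) over PSSM matrices.

The descriptor treats the L x 20 score matrix as a texture image and
summarises it by two local components computed at every cell:

* **differential excitation** xi = arctan(sum_j (x_j - x_i) / x_i) over
  the 8-neighbour ring, a Weber-law relative-change measure bounded in
  [-pi/2, pi/2];
* **orientation** gamma = atan2(v_vert, v_horiz) + pi in [0, 2pi), where
  the two responses come from the 3x3 Sobel derivative pair (the
  "improved" part: all 8 neighbours contribute, which suppresses noise
  relative to 4-neighbour gradients).

Each cell's (xi, gamma) is quantised into an M x T joint histogram; the
matrix is split into V x H sub-blocks whose histograms are concatenated,
giving an M*T*V*H-length feature (256 at the defaults M=T=8, V=H=2).
Two per-protein descriptors concatenated describe a protein pair (512).

Because raw PSSM scores may be zero or negative while the excitation
denominator must stay positive, scores are first passed through the
elementwise logistic map 1/(1+exp(-s)) into (0, 1); this is
order-preserving and can be disabled (``scale=False``) to run on raw
scores with only the epsilon guard.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .pssm import PSSM

__all__ = [
    "IWLDParams",
    "IWLDescriptor",
    "scale_matrix",
    "differential_excitation",
    "orientation",
    "quantize_excitation",
    "quantize_orientation",
    "block_histogram",
    "iwld_features",
    "pair_feature",
]

#: 3x3 Sobel kernel for the horizontal derivative (responds to
#: left-to-right intensity increase); the vertical kernel is its transpose.
SOBEL_H = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float)
SOBEL_V = SOBEL_H.T

#: All-ones 3x3 ring used for the excitation numerator sum(x_j - x_i).
RING_SUM = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=float)


@dataclass(frozen=True)
class IWLDParams:
    """Descriptor binning parameters.

    M and T are the excitation and orientation bin counts; V and H the
    number of vertical (row) and horizontal (column) sub-blocks. The
    defaults give the standard 8*8*2*2 = 256-length descriptor. epsilon
    guards the excitation denominator; scale toggles the logistic
    intensity map; normalize switches the histogram from raw counts to
    per-block L1 frequencies.
    """

    M: int = 8
    T: int = 8
    V: int = 2
    H: int = 2
    epsilon: float = 1e-8
    scale: bool = True
    normalize: bool = False

    def __post_init__(self) -> None:
        for name in ("M", "T", "V", "H"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.epsilon <= 0:
            raise ValueError(f"epsilon must be > 0, got {self.epsilon}")

    @property
    def n_bins(self) -> int:
        return self.M * self.T * self.V * self.H


@dataclass(frozen=True)
class IWLDescriptor:
    """Flattened block histogram of one PSSM (length M*T*V*H)."""

    values: np.ndarray
    params: IWLDParams = field(default_factory=IWLDParams)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size != self.params.n_bins:
            raise ValueError(
                f"descriptor length {values.size} != M*T*V*H = {self.params.n_bins}"
            )
        if np.any(values < 0):
            raise ValueError("descriptor entries must be nonnegative")
        object.__setattr__(self, "values", values)


def scale_matrix(p: PSSM) -> np.ndarray:
    """Map integer scores into (0, 1) with the elementwise logistic
    1/(1+exp(-s)); strictly positive and order-preserving, so the
    excitation denominator is well defined."""
    return 1.0 / (1.0 + np.exp(-p.scores.astype(float)))


def differential_excitation(m: np.ndarray, epsilon: float = 1e-8) -> np.ndarray:
    """Differential excitation xi at every cell.

    xi(x_i) = arctan( sum_{j=0..7} (x_j - x_i) / max(x_i, epsilon) ) over
    the full 3x3 neighbour ring, borders replicate-padded so edge cells
    also see 8 neighbours. Output lies in [-pi/2, pi/2] everywhere.
    """
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError(f"need a matrix of at least 2x2, got shape {m.shape}")
    neighbor_sum = ndimage.correlate(m, RING_SUM, mode="nearest")
    numerator = neighbor_sum - 8.0 * m
    denominator = np.maximum(m, epsilon)
    return np.arctan(numerator / denominator)


def orientation(m: np.ndarray) -> np.ndarray:
    """Gradient orientation gamma at every cell, in [0, 2pi).

    gamma = atan2(v_vert, v_horiz) + pi, where v_horiz and v_vert are the
    horizontal and vertical Sobel responses (replicate-padded borders);
    the seam value 2pi wraps to 0. Flat regions (both responses zero) map
    deterministically to gamma = pi via the atan2(0, 0) = 0 convention.
    """
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError(f"need a matrix of at least 2x2, got shape {m.shape}")
    v10 = ndimage.correlate(m, SOBEL_H, mode="nearest")
    v11 = ndimage.correlate(m, SOBEL_V, mode="nearest")
    # snap accumulated rounding dust to exact zero so flat regions hit the
    # atan2(0, 0) = 0 convention instead of a direction chosen by noise
    tol = 1e-10 * max(1.0, float(np.abs(m).max()))
    v10[np.abs(v10) < tol] = 0.0
    v11[np.abs(v11) < tol] = 0.0
    gamma = np.arctan2(v11, v10) + np.pi
    return np.mod(gamma, 2.0 * np.pi)


def quantize_excitation(xi: np.ndarray | float, M: int = 8) -> np.ndarray | int:
    """Bin excitation values into m in {0..M-1}.

    Bin m covers [ (m/M - 1/2)pi, ((m+1)/M - 1/2)pi ), i.e. uniform bins
    over [-pi/2, pi/2] with the top boundary closed into the last bin.
    """
    arr = np.asarray(xi, dtype=float)
    if np.any(arr < -np.pi / 2 - 1e-12) or np.any(arr > np.pi / 2 + 1e-12):
        raise ValueError("excitation values must lie in [-pi/2, pi/2]")
    m = np.floor((arr + np.pi / 2) / (np.pi / M)).astype(np.int64)
    m = np.clip(m, 0, M - 1)
    return int(m) if np.isscalar(xi) or arr.ndim == 0 else m


def quantize_orientation(gamma: np.ndarray | float, T: int = 8) -> np.ndarray | int:
    """Bin orientations into the nearest of T dominant directions
    Phi_t = 2*pi*t/T, with wraparound: t = floor(gamma/(2pi/T) + 1/2) mod T."""
    arr = np.asarray(gamma, dtype=float)
    if np.any(arr < 0) or np.any(arr >= 2 * np.pi):
        raise ValueError("orientation values must lie in [0, 2pi)")
    t = np.mod(np.floor(arr / (2 * np.pi / T) + 0.5).astype(np.int64), T)
    return int(t) if np.isscalar(gamma) or arr.ndim == 0 else t


def _band_edges(n: int, k: int) -> list[slice]:
    """Split n items into k contiguous bands of size floor(n/k), the
    remainder going to the last band."""
    size = n // k
    edges = []
    for i in range(k):
        start = i * size
        stop = (i + 1) * size if i < k - 1 else n
        edges.append(slice(start, stop))
    return edges


def block_histogram(
    xi_field: np.ndarray,
    gamma_field: np.ndarray,
    params: IWLDParams = IWLDParams(),
) -> IWLDescriptor:
    """Joint (m, t) histogram per V x H sub-block, concatenated.

    Rows are split into V contiguous bands and columns into H bands
    (remainders to the last band); each block contributes an M x T count
    histogram flattened m-major, and blocks are concatenated row-band
    first. In raw-count mode the total equals the number of matrix cells.
    """
    xi_field = np.asarray(xi_field, dtype=float)
    gamma_field = np.asarray(gamma_field, dtype=float)
    if xi_field.shape != gamma_field.shape:
        raise ValueError(
            f"field shapes differ: {xi_field.shape} vs {gamma_field.shape}"
        )
    n_rows, n_cols = xi_field.shape
    if n_rows < params.V:
        raise ValueError(f"matrix has {n_rows} rows but V={params.V} blocks")
    if n_cols < params.H:
        raise ValueError(f"matrix has {n_cols} cols but H={params.H} blocks")

    m_idx = quantize_excitation(xi_field, params.M)
    t_idx = quantize_orientation(gamma_field, params.T)
    joint = m_idx * params.T + t_idx  # m-major flattening of the M x T grid

    chunks = []
    for rband in _band_edges(n_rows, params.V):
        for cband in _band_edges(n_cols, params.H):
            block = joint[rband, cband].ravel()
            hist = np.bincount(block, minlength=params.M * params.T).astype(float)
            if params.normalize:
                total = hist.sum()
                if total > 0:
                    hist = hist / total
            chunks.append(hist)
    return IWLDescriptor(values=np.concatenate(chunks), params=params)


def iwld_features(p: PSSM, params: IWLDParams = IWLDParams()) -> IWLDescriptor:
    """Full descriptor of one PSSM: scale, excitation + orientation,
    quantise, block histogram. Deterministic."""
    matrix = scale_matrix(p) if params.scale else p.scores.astype(float)
    xi = differential_excitation(matrix, params.epsilon)
    gamma = orientation(matrix)
    return block_histogram(xi, gamma, params)


def pair_feature(a: IWLDescriptor, b: IWLDescriptor) -> np.ndarray:
    """Concatenate the two per-protein descriptors of a pair, first
    protein first (length 2*M*T*V*H; 512 at defaults)."""
    if a.params != b.params:
        raise ValueError("descriptors were computed with different parameters")
    return np.concatenate([a.values, b.values])
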