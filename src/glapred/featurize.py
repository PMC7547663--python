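"""Position-based statistical-moment features for peptide windows.

Each 41-mer window is encoded three ways and each encoding is reduced to the
same fixed set of 24 statistical moments:

1. the window itself, written row-major into a small square integer matrix
   (side 7 by default, the smallest square holding 41 cells);
2. its 20x20 position relative incidence matrix (PRIM), which accumulates
   relative positional offsets between amino-acid pairs;
3. the reverse PRIM (RPRIM), the PRIM of the reversed window.

The 24 moments per matrix are raw, central and Hahn moments (8 each) over a
fixed set of order pairs up to total order three. Concatenation gives a
72-dimensional feature vector per window.

Index conventions follow the defining sums: raw and central moments run the
row/column indices b, q over 1..n, while the Hahn transform runs them over
0..N-1.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from functools import lru_cache
from math import lgamma
from pathlib import Path

import numpy as np
import pandas as pd

from .seqio import AMINO_ACIDS, PAD, PeptideWindow

logger = logging.getLogger(__name__)

#: Residue -> integer code, 1..20 in alphabetical order; pad symbol -> 0.
RESIDUE_CODES = {aa: i + 1 for i, aa in enumerate(AMINO_ACIDS)}
RESIDUE_CODES[PAD] = 0

#: Default moment order pairs: the seven orders up to total order three that
#: the moment families are evaluated at, plus (0,0), giving 8 per family and
#: 24 per matrix over the three families.
DEFAULT_ORDERS: tuple[tuple[int, int], ...] = (
    (0, 0), (0, 1), (1, 0), (1, 1), (1, 2), (2, 1), (3, 0), (0, 3),
)

MAX_MOMENT_ORDER = 3

_N_RESIDUES = len(AMINO_ACIDS)


# ---------------------------------------------------------------------------
# Window -> integer matrix
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SequenceMatrix:
    """A peptide window written row-major into an n x n integer grid."""

    values: np.ndarray
    n: int

    def __post_init__(self) -> None:
        if self.values.shape != (self.n, self.n):
            raise ValueError(f"values must be {self.n}x{self.n}")


def encode_residues(window: PeptideWindow) -> np.ndarray:
    """Map window residues to integer codes 1..20 (alphabetical); 'X' -> 0."""
    try:
        return np.array([RESIDUE_CODES[ch] for ch in window.residues], dtype=int)
    except KeyError as exc:
        raise ValueError(f"unexpected residue {exc.args[0]!r}") from exc


def sequence_to_matrix(window: PeptideWindow, n: int = 7) -> SequenceMatrix:
    """Write the window's integer codes row-major into an n x n grid.

    Cells past the window length are zero.
    """
    codes = encode_residues(window)
    if n * n < len(codes):
        raise ValueError(f"matrix side {n} too small for a window of length {len(codes)}")
    grid = np.zeros(n * n, dtype=float)
    grid[: len(codes)] = codes
    return SequenceMatrix(values=grid.reshape(n, n), n=n)


def _as_array(matrix: SequenceMatrix | np.ndarray) -> np.ndarray:
    values = matrix.values if isinstance(matrix, SequenceMatrix) else np.asarray(matrix, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError(f"expected a square 2-D matrix, got shape {values.shape}")
    return values


def _check_orders(orders) -> tuple[tuple[int, int], ...]:
    orders = tuple((int(i), int(j)) for i, j in orders)
    for i, j in orders:
        if i < 0 or j < 0 or i + j > MAX_MOMENT_ORDER:
            raise ValueError(
                f"moment order ({i},{j}) outside the supported range "
                f"(i, j >= 0 and i + j <= {MAX_MOMENT_ORDER})"
            )
    return orders


# ---------------------------------------------------------------------------
# Raw and central moments (indices 1..n)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MomentSet:
    """Ordered moment values of one matrix for one family."""

    family: str
    orders: tuple[tuple[int, int], ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        if len(self.values) != len(self.orders):
            raise ValueError("values and orders must align")


def raw_moments(matrix, orders=DEFAULT_ORDERS) -> MomentSet:
    """Raw moments M_ij = sum_b sum_q b^i q^j beta_bq, b and q in 1..n."""
    beta = _as_array(matrix)
    orders = _check_orders(orders)
    n = beta.shape[0]
    idx = np.arange(1, n + 1, dtype=float)
    values = np.array(
        [float((idx**i) @ beta @ (idx**j)) for i, j in orders]
    )
    return MomentSet(family="raw", orders=orders, values=values)


def central_moments(matrix, orders=DEFAULT_ORDERS) -> MomentSet:
    """Central moments about the intensity centroid (x̄ = M10/M00, ȳ = M01/M00).

    For an all-zero matrix the centroid is undefined; it falls back to the
    matrix centre ((n+1)/2, (n+1)/2) with a logged note.
    """
    beta = _as_array(matrix)
    orders = _check_orders(orders)
    n = beta.shape[0]
    idx = np.arange(1, n + 1, dtype=float)
    m00 = float(beta.sum())
    if m00 == 0.0:
        logger.info("zero-mass matrix: centroid falls back to the matrix centre")
        xbar = ybar = (n + 1) / 2.0
    else:
        xbar = float(idx @ beta.sum(axis=1)) / m00
        ybar = float(beta.sum(axis=0) @ idx) / m00
    values = np.array(
        [float(((idx - xbar) ** i) @ beta @ ((idx - ybar) ** j)) for i, j in orders]
    )
    return MomentSet(family="central", orders=orders, values=values)


# ---------------------------------------------------------------------------
# Hahn polynomials and moments (indices 0..N-1)
# ---------------------------------------------------------------------------

def _pochhammer(a: float, k: int) -> float:
    """Rising factorial (a)_k = a (a+1) ... (a+k-1); (a)_0 = 1."""
    p = 1.0
    for i in range(k):
        p *= a + i
    return p


def hahn_polynomial(n: int, r: int, N: int, u: float = 0.0, v: float = 0.0) -> float:
    """Discrete Hahn polynomial h_n^{u,v}(r, N), evaluated term by term.

    h_n = (N+v-1)_n (N-1)_n * sum_{k=0}^{n} (-1)^k
          [(-n)_k (-r)_k (2N+u+v-n-1)_k] / [(N+v-1)_k (N-1)_k k!]

    Successive series terms are built from the previous one by a ratio of
    small factors, which keeps the evaluation sign-exact and overflow-free
    for large N.
    """
    if not 0 <= n <= N - 1:
        raise ValueError(f"order n={n} outside [0, {N - 1}]")
    if not 0 <= r <= N - 1:
        raise ValueError(f"argument r={r} outside [0, {N - 1}]")
    prefactor = _pochhammer(N + v - 1, n) * _pochhammer(N - 1, n)
    total = 1.0  # k = 0 term: all Pochhammer factors are empty products
    term = 1.0
    for k in range(1, n + 1):
        num = (-n + k - 1) * (-r + k - 1) * (2 * N + u + v - n - 1 + k - 1)
        den = (N + v - 1 + k - 1) * (N - 1 + k - 1) * k
        term *= -num / den
        total += term
    return prefactor * total


def _hahn_weight(r: np.ndarray, N: int, u: float, v: float) -> np.ndarray:
    # classical Hahn weight rho(r) ∝ C(u+r, r) C(v+N-1-r, N-1-r)
    lg = np.vectorize(lgamma)
    return np.exp(
        lg(u + r + 1) - lg(r + 1) + lg(v + N - r) - lg(N - r)
    )


@dataclass(frozen=True)
class HahnBasis:
    """Orthonormal discrete Hahn basis over r = 0..N-1.

    Row ``n`` of ``table`` holds the normalized values h̃_n(r). The raw
    polynomial rows are scaled by the square root of the Hahn weight and then
    orthonormalized by QR in degree order, which fixes the orthonormal family
    uniquely up to sign (signs chosen so each row's leading projection is
    positive). Rows are pairwise orthonormal under the plain discrete inner
    product, so the full-order moment transform is exactly invertible.
    """

    N: int
    u: float
    v: float
    table: np.ndarray

    @classmethod
    def build(cls, N: int, u: float = 0.0, v: float = 0.0) -> "HahnBasis":
        if N < 1:
            raise ValueError("N must be >= 1")
        raw = np.array(
            [[hahn_polynomial(n, r, N, u, v) for r in range(N)] for n in range(N)]
        )
        weighted = raw * np.sqrt(_hahn_weight(np.arange(N, dtype=float), N, u, v))
        q, rmat = np.linalg.qr(weighted.T)
        signs = np.sign(np.diag(rmat))
        signs[signs == 0] = 1.0
        return cls(N=N, u=float(u), v=float(v), table=(q * signs).T)


@lru_cache(maxsize=32)
def get_hahn_basis(N: int, u: float = 0.0, v: float = 0.0) -> HahnBasis:
    """Cached :meth:`HahnBasis.build`."""
    return HahnBasis.build(N, u, v)


def hahn_moments(matrix, basis: HahnBasis, orders=DEFAULT_ORDERS) -> MomentSet:
    """Normalized Hahn moments H_ij = sum_q sum_b beta_qb h̃_i(q) h̃_j(b)."""
    beta = _as_array(matrix)
    if basis.N != beta.shape[0]:
        raise ValueError(f"basis size {basis.N} does not match matrix side {beta.shape[0]}")
    orders = _check_orders(orders)
    full = basis.table @ beta @ basis.table.T
    values = np.array([full[i, j] for i, j in orders])
    return MomentSet(family="hahn", orders=orders, values=values)


def hahn_reconstruct(moments: np.ndarray, basis: HahnBasis) -> np.ndarray:
    """Invert the full-order Hahn transform (orthonormality of the basis)."""
    moments = np.asarray(moments, dtype=float)
    if moments.shape != (basis.N, basis.N):
        raise ValueError("full N x N moment matrix required for reconstruction")
    return basis.table.T @ moments @ basis.table


# ---------------------------------------------------------------------------
# PRIM / RPRIM
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IncidenceMatrix:
    """20x20 accumulator of relative positional offsets between residue pairs.

    Entry (i, j) sums, over every occurrence of residue j strictly after the
    first occurrence of residue i, the positional offset from that first
    occurrence. Rows/columns follow alphabetical residue order; rows for
    absent residues are zero. Pad symbols are ignored (window positions are
    retained).
    """

    values: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        if self.values.shape != (_N_RESIDUES, _N_RESIDUES):
            raise ValueError("incidence matrix must be 20x20")
        if self.kind not in ("PRIM", "RPRIM"):
            raise ValueError(f"kind must be PRIM or RPRIM, got {self.kind!r}")


def _prim_of_residues(residues: str, kind: str) -> IncidenceMatrix:
    occurrences: dict[str, list[int]] = {}
    for pos, ch in enumerate(residues, start=1):
        if ch == PAD:
            continue
        occurrences.setdefault(ch, []).append(pos)
    values = np.zeros((_N_RESIDUES, _N_RESIDUES))
    for aa_i, pos_list in occurrences.items():
        first = pos_list[0]
        row = RESIDUE_CODES[aa_i] - 1
        for aa_j, positions in occurrences.items():
            col = RESIDUE_CODES[aa_j] - 1
            values[row, col] = sum(p - first for p in positions if p > first)
    return IncidenceMatrix(values=values, kind=kind)


def compute_prim(window: PeptideWindow) -> IncidenceMatrix:
    """Position relative incidence matrix (PRIM) of a window."""
    return _prim_of_residues(window.residues, "PRIM")


def compute_rprim(window: PeptideWindow) -> IncidenceMatrix:
    """Reverse PRIM: the PRIM of the reversed residue string."""
    return _prim_of_residues(window.residues[::-1], "RPRIM")


# ---------------------------------------------------------------------------
# Moment reduction and feature assembly
# ---------------------------------------------------------------------------

def reduce_matrix(matrix, orders=DEFAULT_ORDERS, u: float = 0.0, v: float = 0.0) -> np.ndarray:
    """Reduce a square matrix to 24 values: raw ++ central ++ Hahn moments."""
    beta = _as_array(matrix)
    orders = _check_orders(orders)
    basis = get_hahn_basis(beta.shape[0], u, v)
    return np.concatenate(
        [
            raw_moments(beta, orders).values,
            central_moments(beta, orders).values,
            hahn_moments(beta, basis, orders).values,
        ]
    )


@dataclass(frozen=True)
class FeaturizeConfig:
    """Feature-extraction options.

    ``n`` is the side of the window matrix (default 7, the smallest square
    holding 41 cells); ``u``/``v`` are the Hahn parameters (default 0, the
    uniform-weight case); ``orders`` is the moment order set.
    """

    n: int = 7
    u: float = 0.0
    v: float = 0.0
    orders: tuple[tuple[int, int], ...] = DEFAULT_ORDERS


@dataclass(frozen=True)
class FeatureVector:
    """Ordered feature values with named segment boundaries."""

    values: np.ndarray
    layout: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        if sum(size for _, size in self.layout) != len(self.values):
            raise ValueError("layout does not match values length")


_SEGMENTS = ("win", "prim", "rprim")
_FAMILIES = ("raw", "central", "hahn")


def feature_names(config: FeaturizeConfig | None = None) -> list[str]:
    """Column names like ``win_raw_00`` ... ``rprim_hahn_03``."""
    config = config or FeaturizeConfig()
    return [
        f"{segment}_{family}_{i}{j}"
        for segment in _SEGMENTS
        for family in _FAMILIES
        for i, j in config.orders
    ]


def featurize(window: PeptideWindow, config: FeaturizeConfig | None = None) -> FeatureVector:
    """Full feature vector of one window: window, PRIM and RPRIM moments."""
    config = config or FeaturizeConfig()
    win = sequence_to_matrix(window, n=config.n)
    parts = [
        reduce_matrix(win.values, config.orders, config.u, config.v),
        reduce_matrix(compute_prim(window).values, config.orders, config.u, config.v),
        reduce_matrix(compute_rprim(window).values, config.orders, config.u, config.v),
    ]
    layout = tuple((seg, len(part)) for seg, part in zip(_SEGMENTS, parts))
    return FeatureVector(values=np.concatenate(parts), layout=layout)


def featurize_windows(
    windows: list[PeptideWindow], config: FeaturizeConfig | None = None
) -> pd.DataFrame:
    """Feature table for a window list: named feature columns plus
    ``label``, ``source_id`` and ``center_position``."""
    config = config or FeaturizeConfig()
    rows = np.array([featurize(w, config).values for w in windows])
    frame = pd.DataFrame(rows, columns=feature_names(config))
    frame["label"] = [w.label for w in windows]
    frame["source_id"] = [w.source_id for w in windows]
    frame["center_position"] = [w.center_position for w in windows]
    return frame


def split_feature_frame(frame: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """(X, y) from a feature table produced by :func:`featurize_windows`."""
    meta = ["label", "source_id", "center_position"]
    X = frame.drop(columns=[c for c in meta if c in frame.columns]).to_numpy(dtype=float)
    y = frame["label"].to_numpy(dtype=int)
    return X, y


# ---------------------------------------------------------------------------
# Feature scaling
# ---------------------------------------------------------------------------

@dataclass
class ScalerParams:
    """Per-feature scaling statistics fitted on training data.

    ``standard`` centres to mean 0 / variance 1; ``minmax`` maps the training
    range to [0, 1]: X_norm = (X - X_min) / (X_max - X_min). Constant features
    map to 0 in both modes.
    """

    mode: str
    center: np.ndarray  # mean (standard) or min (minmax)
    scale: np.ndarray   # std (standard) or range (minmax); 0 kept as fitted

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "mode": self.mode,
                    "center": self.center.tolist(),
                    "scale": self.scale.tolist(),
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "ScalerParams":
        data = json.loads(Path(path).read_text())
        return cls(
            mode=data["mode"],
            center=np.array(data["center"], dtype=float),
            scale=np.array(data["scale"], dtype=float),
        )


def _as_matrix(vectors) -> np.ndarray:
    if isinstance(vectors, np.ndarray):
        X = vectors
    else:
        X = np.array(
            [v.values if isinstance(v, FeatureVector) else v for v in vectors],
            dtype=float,
        )
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("a non-empty 2-D feature matrix is required")
    return np.asarray(X, dtype=float)


def fit_scaler(vectors, mode: str = "standard") -> ScalerParams:
    """Fit per-feature scaling statistics (training data only)."""
    if mode not in ("standard", "minmax"):
        raise ValueError(f"mode must be 'standard' or 'minmax', got {mode!r}")
    X = _as_matrix(vectors)
    if mode == "standard":
        center, scale = X.mean(axis=0), X.std(axis=0)
    else:
        center = X.min(axis=0)
        scale = X.max(axis=0) - center
    return ScalerParams(mode=mode, center=center, scale=scale)


def apply_scaler(params: ScalerParams, vectors) -> np.ndarray:
    """Scale a feature matrix with fitted statistics; constant features -> 0."""
    X = _as_matrix(vectors)
    if X.shape[1] != len(params.center):
        raise ValueError(
            f"feature count {X.shape[1]} does not match fitted statistics "
            f"({len(params.center)})"
        )
    safe = np.where(params.scale == 0, 1.0, params.scale)
    return (X - params.center) / safe


def inverse_scale(params: ScalerParams, scaled) -> np.ndarray:
    """Undo :func:`apply_scaler` (exact for non-constant features)."""
    X = _as_matrix(scaled)
    safe = np.where(params.scale == 0, 1.0, params.scale)
    return X * safe + params.center
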