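"""Joint chest/core oscillation dynamics via PCA of cosinor parameters.

Each subject with both channels contributes one row of ten cosinor
parameters, in the immutable column order::

    [M, a1, b1, a2, b2]_chest  ++  [M, a1, b1, a2, b2]_core

Standard PCA is applied to the column-standardised matrix (mean 0, sample
sd 1).  Because the fitted temperature curves are linear in the cosinor
parameters, any point in parameter space maps to a closed planar curve —
the 24-h "loop" traced by (chest ŷ(t), core ŷ(t)) — so single principal
components can be visualised as families of loops swept by their score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cosinor import CosinorFit, _design
from .series import PROFILE_BIN_MINUTES

MATRIX_COLUMNS = [
    f"{ch}_{p}" for ch in ("chest", "core") for p in ("M", "a1", "b1", "a2", "b2")
]


@dataclass
class CosinorMatrix:
    """Subjects × 10 cosinor-parameter matrix with retained column stats."""

    data: pd.DataFrame  # rows indexed by subject id, columns MATRIX_COLUMNS

    def __post_init__(self) -> None:
        if list(self.data.columns) != MATRIX_COLUMNS:
            raise ValueError(f"columns must be exactly {MATRIX_COLUMNS}")
        if self.data.isna().any().any():
            raise ValueError("cosinor matrix must have no missing cells")

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class PCModel:
    """Principal components of the standardised cosinor matrix.

    ``loadings`` (10 × n_pc) are orthonormal eigenvectors of the correlation
    structure with a deterministic sign convention: the largest-magnitude
    element of each loading vector is positive.  ``scores`` are the
    principal-component coordinates of the standardised rows.
    """

    loadings: np.ndarray
    scores: pd.DataFrame  # rows = subjects, columns PC1..PCk
    variance_fractions: np.ndarray
    column_means: np.ndarray
    column_sds: np.ndarray

    @property
    def n_pc(self) -> int:
        return self.loadings.shape[1]


def assemble_matrix(fits: dict) -> CosinorMatrix:
    """Pool per-subject chest and core fits into the 10-column matrix.

    ``fits`` maps subject id -> {"chest": CosinorFit, "core": CosinorFit}.
    Subjects missing either channel are dropped with a warning; fewer than
    3 complete subjects or duplicated parameter rows are rejected.
    """
    rows, index, dropped = [], [], []
    for sid, pair in fits.items():
        chest, core = pair.get("chest"), pair.get("core")
        if not isinstance(chest, CosinorFit) or not isinstance(core, CosinorFit):
            dropped.append(sid)
            continue
        rows.append(np.concatenate([chest.params, core.params]))
        index.append(sid)
    if dropped:
        warnings.warn(
            f"dropped {len(dropped)} subject(s) lacking a channel: {dropped}",
            stacklevel=2,
        )
    if len(rows) < 3:
        raise ValueError("PCA needs at least 3 subjects with both channels")
    arr = np.vstack(rows)
    if len(np.unique(arr, axis=0)) < len(arr):
        raise ValueError("duplicate subject parameter rows detected")
    return CosinorMatrix(pd.DataFrame(arr, index=index, columns=MATRIX_COLUMNS))


def run_pca(matrix: CosinorMatrix) -> PCModel:
    """Centered/scaled PCA of the cosinor matrix (SVD of the z-scores)."""
    X = matrix.values
    n = len(X)
    if n < 3:
        raise ValueError("PCA needs at least 3 rows")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    zero = np.flatnonzero(sds == 0)
    if len(zero):
        names = [MATRIX_COLUMNS[i] for i in zero]
        raise ValueError(f"zero-variance column(s): {names}")
    Z = (X - means) / sds
    _, s, vt = np.linalg.svd(Z, full_matrices=False)
    k = min(n - 1, Z.shape[1])
    loadings = vt[:k].T
    # deterministic signs: largest-|.| element of each loading positive
    for j in range(k):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] = -loadings[:, j]
    scores = Z @ loadings
    var_frac = s[:k] ** 2 / np.sum(s**2)
    return PCModel(
        loadings=loadings,
        scores=pd.DataFrame(
            scores, index=matrix.data.index, columns=[f"PC{j + 1}" for j in range(k)]
        ),
        variance_fractions=var_frac,
        column_means=means,
        column_sds=sds,
    )


def _loop_from_params(params10: np.ndarray, grid_minutes: float = PROFILE_BIN_MINUTES) -> pd.DataFrame:
    """Closed (chest, core) curve over 24 h from a 10-parameter vector."""
    t = np.arange(0.0, 24.0 + 1e-9, grid_minutes / 60.0)
    t[-1] = 24.0  # close the loop exactly: y(24) == y(0) by periodicity
    X = _design(t)
    chest = X @ params10[:5]
    core = X @ params10[5:]
    return pd.DataFrame({"t_hours": t, "chest": chest, "core": core})


def reconstruct_loop(
    model: PCModel, pc_index: int, score: float, grid_minutes: float = PROFILE_BIN_MINUTES
) -> pd.DataFrame:
    """Single-PC 24-h loop at a given score.

    The parameter vector is ``column_means + score · (loading ∘ column_sds)``
    (back-transformed from the standardised space); at score 0 every PC
    yields the cohort-mean loop.  ``pc_index`` is 1-based.
    """
    if not (1 <= pc_index <= model.n_pc):
        raise ValueError(f"pc_index must be in 1..{model.n_pc}")
    if not np.isfinite(score):
        raise ValueError("score must be finite")
    params = model.column_means + score * model.loadings[:, pc_index - 1] * model.column_sds
    return _loop_from_params(params, grid_minutes)


def loop_from_scores(
    model: PCModel, scores: np.ndarray, grid_minutes: float = PROFILE_BIN_MINUTES
) -> pd.DataFrame:
    """Loop reconstructed from a full score vector (all PCs at once).

    With a subject's own scores this reproduces that subject's fitted loop
    exactly (basis completeness).
    """
    scores = np.asarray(scores, dtype=float)
    if len(scores) != model.n_pc:
        raise ValueError(f"expected {model.n_pc} scores")
    params = model.column_means + (model.loadings @ scores) * model.column_sds
    return _loop_from_params(params, grid_minutes)
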