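"""Protected-attribute oversampling with a from-scratch SMOTE-NC sampler.

The balancing scheme equalizes SES-group representation in the *training*
partition while preserving the case/control ratio: synthetic low-SES rows
are generated independently within each (low-SES x outcome) cell until the
low-SES total equals the high-SES total and the low-SES case fraction is
unchanged (to within one sample).  The test partition is never touched.

The sampler handles mixed continuous/nominal features.  Distances between
rows are

    sqrt( sum of squared continuous differences
          + (number of nominal mismatches) * med^2 )

where ``med`` is the median of the standard deviations of the cell's
continuous features.  A synthetic row interpolates the continuous block
between a seed row and one of its k nearest within-cell neighbors
(uniform fraction), and takes each nominal entry by majority vote among the
k neighbors (ties broken toward the lowest value).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.neighbors import NearestNeighbors

from .config import MitigationConfig
from .exceptions import InfeasibleBalanceError


def median_std(X_cont: np.ndarray) -> float:
    """Median of per-feature standard deviations (population convention)."""
    X_cont = np.asarray(X_cont, dtype=float)
    if X_cont.ndim != 2 or X_cont.shape[1] == 0:
        raise ValueError("median_std needs a 2-D array with >= 1 continuous column")
    return float(np.median(X_cont.std(axis=0)))


def mixed_distance(
    row_a,
    row_b,
    continuous_idx,
    nominal_idx,
    med: float,
) -> float:
    """SMOTE-NC distance between two mixed rows (see module docstring)."""
    a = np.asarray(row_a, dtype=float)
    b = np.asarray(row_b, dtype=float)
    if len(continuous_idx) == 0 and not np.isfinite(med):
        raise ValueError("no continuous features and med undefined")
    cont = float(np.sum((a[continuous_idx] - b[continuous_idx]) ** 2))
    mismatches = int(np.sum(a[nominal_idx] != b[nominal_idx]))
    return float(np.sqrt(cont + mismatches * med**2))


def _encode_for_knn(
    X: np.ndarray, continuous_idx: np.ndarray, nominal_idx: np.ndarray, med: float
) -> np.ndarray:
    """Embed mixed rows so Euclidean distance equals :func:`mixed_distance`.

    Binary nominal columns are scaled by ``med``; multi-valued nominal
    columns are one-hot encoded and scaled by ``med/sqrt(2)`` so each
    mismatch contributes exactly ``med**2``.
    """
    blocks = [X[:, continuous_idx]]
    for j in nominal_idx:
        col = X[:, j]
        values = np.unique(col)
        if len(values) <= 2:
            codes = (col == values[-1]).astype(float) if len(values) else col
            blocks.append((codes * med)[:, None])
        else:
            onehot = (col[:, None] == values[None, :]).astype(float)
            blocks.append(onehot * (med / np.sqrt(2.0)))
    return np.hstack(blocks)


@dataclass
class SyntheticSample:
    """Provenance of one synthetic row."""

    seed_row: int
    neighbor_row: int
    fraction: float


def synthesize_rows(
    X_cell: np.ndarray,
    n_samples: int,
    continuous_idx: np.ndarray,
    nominal_idx: np.ndarray,
    k_neighbors: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[SyntheticSample], int]:
    """Generate ``n_samples`` synthetic rows within one minority cell.

    Returns (rows, provenance, k_used).  When the cell holds fewer than
    k+1 rows, k is reduced (never fabricating neighbors); a single-row cell
    cannot be oversampled.
    """
    n_cell = X_cell.shape[0]
    if n_cell < 2:
        raise InfeasibleBalanceError(
            "cannot synthesize from a cell with fewer than 2 rows"
        )
    k = min(k_neighbors, n_cell - 1)
    med = median_std(X_cell[:, continuous_idx]) if len(continuous_idx) else float("nan")
    emb = _encode_for_knn(X_cell, continuous_idx, nominal_idx, med)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(emb)
    neigh = nn.kneighbors(emb, return_distance=False)[:, 1:]  # drop self

    seeds = rng.integers(0, n_cell, size=n_samples)
    pick = rng.integers(0, k, size=n_samples)
    u = rng.random(n_samples)

    out = np.empty((n_samples, X_cell.shape[1]), dtype=float)
    provenance: list[SyntheticSample] = []
    # majority vote among each seed's k neighbors, ties to the lowest value
    for i in range(n_samples):
        s = seeds[i]
        nb = neigh[s, pick[i]]
        row = X_cell[s].copy()
        row[continuous_idx] = X_cell[s, continuous_idx] + u[i] * (
            X_cell[nb, continuous_idx] - X_cell[s, continuous_idx]
        )
        for j in nominal_idx:
            vals, counts = np.unique(X_cell[neigh[s], j], return_counts=True)
            row[j] = vals[np.argmax(counts)]  # np.unique sorts: ties -> lowest
        out[i] = row
        provenance.append(SyntheticSample(int(s), int(nb), float(u[i])))
    return out, provenance, k


@dataclass
class BalanceResult:
    X: pd.DataFrame
    y: np.ndarray
    ses: np.ndarray
    synthetic: np.ndarray  # boolean flag per output row
    provenance: list[dict] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


class ProtectedGroupSMOTENC(BaseEstimator):
    """SES-group balancing sampler (scikit-learn estimator interface).

    Oversamples the low-SES group to parity with the high-SES group in the
    training data, synthesizing within each (low-SES x outcome) cell so the
    low-SES case/control ratio is preserved to within one sample.

    Parameters
    ----------
    k_neighbors : neighbor count for the SMOTE-NC kernel (default 5).
    random_state : sampler seed (default 42).
    nominal_features : column names treated as categorical; continuous
        entries are interpolated, nominal entries voted.
    """

    def __init__(
        self,
        k_neighbors: int = 5,
        random_state: int = 42,
        nominal_features: list[str] | None = None,
    ) -> None:
        self.k_neighbors = k_neighbors
        self.random_state = random_state
        self.nominal_features = nominal_features

    def fit_resample(self, X: pd.DataFrame, y, *, protected) -> BalanceResult:
        """Balance ``X`` (training features) on the binary ``protected``
        labels ('low'/'high'), preserving the outcome ratio among synthetic
        rows' group.  Rows are processed in sorted row-identifier order so
        the output is independent of input row order."""
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        y_in = np.asarray(y)
        prot_in = np.asarray(protected)
        if len(X) != len(y_in) or len(X) != len(prot_in):
            raise ValueError("X, y and protected must have equal length")
        sort = np.argsort(X.index.to_numpy(), kind="stable")
        X = X.iloc[sort]
        order = X.index
        y = pd.Series(y_in[sort], index=order)
        prot = pd.Series(prot_in[sort], index=order)
        nominal = list(self.nominal_features or [])
        unknown = set(nominal) - set(X.columns)
        if unknown:
            raise ValueError(f"nominal features not in manifest: {sorted(unknown)}")
        cont_idx = np.array([i for i, c in enumerate(X.columns) if c not in nominal])
        nom_idx = np.array(
            [i for i, c in enumerate(X.columns) if c in nominal], dtype=int
        )

        low_mask = (prot == "low").to_numpy()
        n_low, n_high = int(low_mask.sum()), int((~low_mask).sum())
        result_warnings: list[str] = []
        if n_low == 0:
            raise InfeasibleBalanceError("no low-SES rows in the training data")
        if n_low >= n_high:
            return BalanceResult(
                X.copy(), y.to_numpy(), prot.to_numpy(),
                np.zeros(len(X), dtype=bool),
            )

        y_arr = y.to_numpy()
        low_cases = int(((y_arr == 1) & low_mask).sum())
        target_cases = int(round(n_high * low_cases / n_low))
        target_controls = n_high - target_cases
        need = {
            1: max(target_cases - low_cases, 0),
            0: max(target_controls - (n_low - low_cases), 0),
        }
        rng = np.random.default_rng(self.random_state)

        X_new, y_new, prov = [], [], []
        for outcome in (1, 0):
            n_need = need[outcome]
            if n_need == 0:
                continue
            cell_mask = low_mask & (y_arr == outcome)
            if cell_mask.sum() == 0:
                raise InfeasibleBalanceError(
                    f"cannot balance: the (low-SES, outcome={outcome}) cell is empty"
                )
            cell_rows = np.nonzero(cell_mask)[0]
            X_cell = X.iloc[cell_rows].to_numpy(dtype=float)
            rows, cell_prov, k_used = synthesize_rows(
                X_cell, n_need, cont_idx, nom_idx, self.k_neighbors, rng
            )
            if k_used < self.k_neighbors:
                result_warnings.append(
                    f"cell (low, outcome={outcome}) has {len(cell_rows)} rows; "
                    f"k reduced to {k_used}"
                )
            X_new.append(rows)
            y_new.append(np.full(n_need, outcome))
            for p in cell_prov:
                prov.append(
                    {
                        "seed_row": str(order[cell_rows[p.seed_row]]),
                        "neighbor_row": str(order[cell_rows[p.neighbor_row]]),
                        "fraction": p.fraction,
                        "outcome": outcome,
                    }
                )

        if X_new:
            synth_X = pd.DataFrame(
                np.vstack(X_new),
                columns=X.columns,
                index=[f"synthetic_{i}" for i in range(sum(len(b) for b in X_new))],
            )
            X_out = pd.concat([X, synth_X])
            y_out = np.concatenate([y_arr, np.concatenate(y_new)])
            ses_out = np.concatenate(
                [prot.to_numpy(), np.full(len(synth_X), "low", dtype=object)]
            )
            flag = np.concatenate(
                [np.zeros(len(X), dtype=bool), np.ones(len(synth_X), dtype=bool)]
            )
        else:
            X_out, y_out, ses_out = X.copy(), y_arr, prot.to_numpy()
            flag = np.zeros(len(X), dtype=bool)
        return BalanceResult(X_out, y_out, ses_out, flag, prov, result_warnings)


def balance_protected(
    X: pd.DataFrame, y, ses_levels, cfg: MitigationConfig
) -> BalanceResult:
    """Functional wrapper over :class:`ProtectedGroupSMOTENC`."""
    sampler = ProtectedGroupSMOTENC(
        k_neighbors=cfg.k_neighbors,
        random_state=cfg.seed,
        nominal_features=cfg.nominal_features,
    )
    return sampler.fit_resample(X, y, protected=ses_levels)
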