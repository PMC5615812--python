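"""Shared transformations: log10 scaling, interaction expansion,
covariate encoding, residualization, and the train/test split."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "log10_transform",
    "expand_interactions",
    "ExpandedDesign",
    "Standardizer",
    "covariate_design",
    "residualize",
    "ResidualizedData",
    "split_train_test",
]


def log10_transform(cohort):
    """Return a copy of the cohort with exposures and outcome on log10 scale.

    Raises if any value is non-positive (naming the first offending
    row/column) or if the cohort is already transformed.
    """
    from .synthetic import MixtureCohort

    if cohort.log_scale:
        raise ValueError("cohort already log10-transformed")
    E = cohort.exposures
    bad = (E <= 0)
    if bad.any().any():
        col = bad.any(axis=0).idxmax()
        row = int(bad[col].idxmax())
        raise ValueError(f"non-positive exposure at row {row}, column {col!r}")
    if (cohort.outcome <= 0).any():
        row = int((cohort.outcome <= 0).idxmax())
        raise ValueError(f"non-positive outcome at row {row}")
    return MixtureCohort(
        exposures=np.log10(E),
        covariates=cohort.covariates.copy(),
        outcome=np.log10(cohort.outcome),
        binary=cohort.binary,
        survival=cohort.survival,
        lod=cohort.lod,
        truth=cohort.truth,
        log_scale=True,
    )


@dataclass
class ExpandedDesign:
    """Main-effect columns followed by all pairwise product columns.

    Column-name grammar: mains keep their input name ``A``; interactions
    are ``AxB`` with A before B in the input order.  ``index_map`` gives,
    per column, its type and constituent exposures.
    """

    X: np.ndarray
    names: list[str]
    index_map: dict[str, dict] = field(default_factory=dict)

    @property
    def main_names(self) -> list[str]:
        return [n for n in self.names if self.index_map[n]["type"] == "main"]

    def columns(self, names: list[str]) -> np.ndarray:
        pos = {n: i for i, n in enumerate(self.names)}
        missing = [n for n in names if n not in pos]
        if missing:
            raise KeyError(f"design is missing columns: {missing}")
        return self.X[:, [pos[n] for n in names]]


def expand_interactions(E: np.ndarray, names: list[str]) -> ExpandedDesign:
    """All mains plus all pairwise products, deterministic order.

    Mains appear in input order; interactions in lexicographic (k, l),
    k < l, order of the input positions.  For p exposures the design has
    p + p(p-1)/2 columns.
    """
    E = np.asarray(E, dtype=float)
    if E.ndim != 2 or E.shape[1] < 2:
        raise ValueError("E must be n x p with p >= 2")
    p = E.shape[1]
    if len(names) != p:
        raise ValueError("names length must match column count")
    if len(set(names)) != p:
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate exposure names: {dupes}")

    cols = [E]
    out_names = list(names)
    index_map: dict[str, dict] = {
        n: {"type": "main", "exposures": (n,)} for n in names
    }
    inter = np.empty((E.shape[0], p * (p - 1) // 2))
    k = 0
    for i in range(p - 1):
        for j in range(i + 1, p):
            inter[:, k] = E[:, i] * E[:, j]
            nm = f"{names[i]}x{names[j]}"
            out_names.append(nm)
            index_map[nm] = {"type": "interaction", "exposures": (names[i], names[j])}
            k += 1
    cols.append(inter)
    return ExpandedDesign(X=np.hstack(cols), names=out_names, index_map=index_map)


@dataclass
class Standardizer:
    """Column-wise (x - mean) / sd with training-set statistics."""

    mean: np.ndarray | None = None
    sd: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "Standardizer":
        X = np.asarray(X, dtype=float)
        self.mean = X.mean(axis=0)
        sd = X.std(axis=0)
        if (sd == 0).any():
            raise ValueError("constant column cannot be standardized")
        self.sd = sd
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.mean is None:
            raise RuntimeError("Standardizer not fitted")
        return (np.asarray(X, dtype=float) - self.mean) / self.sd

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)


def covariate_design(
    Z: pd.DataFrame, reference: dict[str, object] | None = None
) -> tuple[np.ndarray, list[str]]:
    """Reference-cell indicator encoding of a covariate table.

    Categorical columns expand to indicators dropping the first observed
    level (or the level given in ``reference``); numeric columns pass
    through.  No intercept column is added.
    """
    cols: list[np.ndarray] = []
    names: list[str] = []
    for c in Z.columns:
        s = Z[c]
        if isinstance(s.dtype, pd.CategoricalDtype) or s.dtype == object:
            levels = list(pd.Categorical(s).categories)
            ref = (reference or {}).get(c, levels[0])
            for lev in levels:
                if lev == ref:
                    continue
                cols.append((s == lev).to_numpy(dtype=float))
                names.append(f"{c}[{lev}]")
        else:
            cols.append(s.to_numpy(dtype=float))
            names.append(c)
    X = np.column_stack(cols) if cols else np.empty((len(Z), 0))
    return X, names


@dataclass
class ResidualizedData:
    """OLS residuals of Y and each exposure column on the covariates.

    The projection coefficients are retained so that held-out data can be
    residualized with the training-set fit.
    """

    Y_star: np.ndarray
    E_star: np.ndarray
    coef_y: np.ndarray  # (k+1,) including intercept
    coef_e: np.ndarray  # (k+1, p)
    z_names: list[str]

    def transform(
        self, Y: np.ndarray | None, E: np.ndarray, Z_design: np.ndarray
    ) -> tuple[np.ndarray | None, np.ndarray]:
        """Apply the stored training-set projections to new data."""
        D = np.column_stack([np.ones(len(Z_design)), Z_design])
        E_star = np.asarray(E, dtype=float) - D @ self.coef_e
        Y_star = None
        if Y is not None:
            Y_star = np.asarray(Y, dtype=float) - D @ self.coef_y
        return Y_star, E_star


def residualize(
    Y: np.ndarray, E: np.ndarray, Z_design: np.ndarray, z_names: list[str] | None = None
) -> ResidualizedData:
    """Regress Y and each exposure on the covariates; keep residuals.

    The covariate design (plus intercept) must be full rank; collinear
    columns are reported by name.
    """
    Y = np.asarray(Y, dtype=float)
    E = np.asarray(E, dtype=float)
    Z_design = np.asarray(Z_design, dtype=float)
    n = len(Y)
    D = np.column_stack([np.ones(n), Z_design])
    rank = np.linalg.matrix_rank(D)
    if rank < D.shape[1]:
        names = ["intercept"] + list(
            z_names or [f"z{j}" for j in range(Z_design.shape[1])]
        )
        # identify a maximal independent prefix to name the offenders
        bad = []
        kept: list[int] = []
        for j in range(D.shape[1]):
            trial = kept + [j]
            if np.linalg.matrix_rank(D[:, trial]) < len(trial):
                bad.append(names[j])
            else:
                kept.append(j)
        raise ValueError(f"rank-deficient covariate design; collinear columns: {bad}")
    coef_y, *_ = np.linalg.lstsq(D, Y, rcond=None)
    coef_e, *_ = np.linalg.lstsq(D, E, rcond=None)
    return ResidualizedData(
        Y_star=Y - D @ coef_y,
        E_star=E - D @ coef_e,
        coef_y=coef_y,
        coef_e=coef_e,
        z_names=list(z_names or [f"z{j}" for j in range(Z_design.shape[1])]),
    )


def split_train_test(cohort, ratio: float = 0.5, seed: int = 0):
    """Seeded random split into disjoint, exhaustive train/test cohorts.

    The default 1:1 ratio matches the standard design of fitting every ERS
    on one half and validating on the other.
    """
    if not (0.0 < ratio < 1.0):
        raise ValueError("ratio must be in (0, 1)")
    n = cohort.n
    if n < 2:
        raise ValueError("need at least 2 subjects to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(n * ratio))
    n_train = min(max(n_train, 1), n - 1)
    train_idx = np.sort(perm[:n_train])
    test_idx = np.sort(perm[n_train:])
    return cohort.subset(train_idx), cohort.subset(test_idx)
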