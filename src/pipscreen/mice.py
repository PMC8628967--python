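"""Multiple imputation by chained equations for categorical covariates.

Missingness is assumed MAR.  Only variables whose missingness fraction
exceeds a threshold (default 1%) are imputed; those at or below it are
returned untouched.  Each incomplete variable is modelled by a multinomial
logistic regression on the other analysis variables (one-hot encoded,
outcome and visit included), and missing cells are replaced by draws from
the fitted predictive probabilities.  Sweeps repeat until the chain settles
(a fixed small number of sweeps, standard for chained equations); the whole
procedure is repeated m times with independent RNG streams to give m
completed datasets.  Non-missing cells are never altered.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

__all__ = ["missingness_fractions", "mice_impute"]

_N_SWEEPS = 5


def missingness_fractions(df: pd.DataFrame, variables: Sequence[str]) -> dict[str, float]:
    """Fraction of missing cells per variable."""
    return {v: float(df[v].isna().mean()) for v in variables}


def _predictor_matrix(df: pd.DataFrame, predictors: Sequence[str]) -> np.ndarray:
    blocks = []
    for c in predictors:
        col = df[c]
        if col.dtype.kind in "ifb":
            blocks.append(col.to_numpy(float)[:, None])
        else:
            dummies = pd.get_dummies(col.astype("object"), dummy_na=False)
            blocks.append(dummies.to_numpy(float))
    return np.hstack(blocks) if blocks else np.ones((len(df), 1))


def _impute_once(
    df: pd.DataFrame,
    targets: list[str],
    predictors_for: dict[str, list[str]],
    rng: np.random.Generator,
) -> pd.DataFrame:
    work = df.copy()
    masks = {v: df[v].isna().to_numpy() for v in targets}
    # initialize by drawing from the observed marginal
    for v in targets:
        obs = df[v].dropna()
        if obs.empty:
            raise ValueError(f"variable {v!r} is entirely missing; cannot impute")
        fill = rng.choice(obs.to_numpy(), size=int(masks[v].sum()), replace=True)
        work.loc[masks[v], v] = fill
    for _ in range(_N_SWEEPS):
        for v in targets:
            mask = masks[v]
            if not mask.any():
                continue
            X = _predictor_matrix(work, predictors_for[v])
            y = work[v].astype(str).to_numpy()
            classes = np.unique(y[~mask])
            if len(classes) == 1:
                work.loc[mask, v] = classes[0]
                continue
            model = LogisticRegression(max_iter=500)
            with warnings.catch_warnings():
                # a not-fully-converged conditional model still yields valid
                # draws for the chain; don't surface solver chatter
                warnings.simplefilter("ignore", ConvergenceWarning)
                model.fit(X[~mask], y[~mask])
            proba = model.predict_proba(X[mask])
            cum = proba.cumsum(axis=1)
            draws = rng.random((mask.sum(), 1))
            idx = (draws > cum).sum(axis=1)
            work.loc[mask, v] = model.classes_[idx]
    return work


def mice_impute(
    dataset: pd.DataFrame,
    variables: Sequence[str],
    m: int = 5,
    seed: int = 0,
    *,
    threshold: float = 0.01,
    predictors: Optional[Sequence[str]] = None,
) -> list[pd.DataFrame]:
    """Return m completed copies of *dataset*.

    Parameters
    ----------
    variables
        Candidate variables; only those with missingness strictly above
        *threshold* are imputed (the rest are left untouched, including any
        missing cells they carry).
    m
        Number of completed datasets.
    seed
        Seeds the chained-equation draws; the result is a pure function of
        (dataset, variables, m, seed).
    predictors
        Columns used as predictors in every conditional model; defaults to
        all other candidate variables plus any of pip / sex / age_group /
        visit_month present.
    """
    fractions = missingness_fractions(dataset, variables)
    targets = [v for v in variables if fractions[v] > threshold]
    if not targets:
        return [dataset.copy() for _ in range(m)]
    default_aux = [
        c for c in ("pip", "sex", "age_group", "polypharmacy_category",
                    "charlson_category", "visit_month")
        if c in dataset.columns
    ]
    predictors_for = {
        v: [
            c
            for c in (predictors if predictors is not None else list(variables) + default_aux)
            if c != v and c in dataset.columns
        ]
        for v in targets
    }
    # predictors that are themselves imputation targets are fine: the chain
    # uses their current completed values at each sweep
    root = np.random.default_rng(seed)
    streams = root.spawn(m)
    return [_impute_once(dataset, targets, predictors_for, s) for s in streams]
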