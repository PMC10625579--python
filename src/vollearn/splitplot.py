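"""Mixed (split-plot) factorial ANOVA with Greenhouse-Geisser correction.

Supports any number of between-subject factors and within-subject factors,
each fully crossed, with one observation per subject per within cell.
The analysis follows the classical multivariate-contrast construction:

* within-subject effects are represented by orthonormal contrast sets over
  the within cells (Kronecker products of per-factor contrast bases);
* for each within-effect contrast set, the contrast scores are regressed
  on the effect-coded between-subject design, and each between term is
  tested by a Type-III model comparison (drop the term's columns);
* the regression intercept tests the within effect itself, the between
  terms its interactions with between factors; the contrast set of all
  averaging vectors (the subject means) yields the purely between tests.

Greenhouse-Geisser epsilon is estimated per within effect from the error
covariance of its orthonormal contrasts; effects with a single degree of
freedom have epsilon exactly 1.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["mixed_anova"]


def _orthonormal_contrasts(k: int) -> tuple[np.ndarray, np.ndarray]:
    """(averaging vector (k,1), orthonormal contrast matrix (k, k-1))."""
    mean = np.full((k, 1), 1.0 / np.sqrt(k))
    if k == 1:
        return mean, np.zeros((1, 0))
    # Helmert-style contrasts, orthonormalised
    H = np.zeros((k, k - 1))
    for j in range(k - 1):
        H[: j + 1, j] = 1.0
        H[j + 1, j] = -(j + 1)
    Q, _ = np.linalg.qr(np.hstack([mean, H]))
    return mean, Q[:, 1:]


def _effect_code(values: pd.Series) -> tuple[np.ndarray, list]:
    """Sum-to-zero coding: k-1 columns, last level coded -1 everywhere."""
    levels = sorted(pd.unique(values))
    k = len(levels)
    X = np.zeros((len(values), k - 1))
    arr = np.asarray(values)
    for j, lev in enumerate(levels[:-1]):
        X[arr == lev, j] = 1.0
    X[arr == levels[-1], :] = -1.0
    return X, levels


def _sse(U: np.ndarray, X: np.ndarray) -> float:
    if X.shape[1] == 0:
        return float(np.sum(U * U))
    beta, *_ = np.linalg.lstsq(X, U, rcond=None)
    R = U - X @ beta
    return float(np.sum(R * R))


def _error_cov(U: np.ndarray, X: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(X, U, rcond=None)
    R = U - X @ beta
    return R.T @ R


def mixed_anova(
    data: pd.DataFrame,
    dv: str,
    within: list[str],
    between: list[str],
    subject: str,
) -> pd.DataFrame:
    """Full-factorial mixed ANOVA on a tidy long-format table.

    Subjects with any missing within cell are dropped listwise.  Returns
    one row per effect with columns effect, df_num, df_den, F, p,
    gg_epsilon, p_gg, ss_effect, ss_error.  Raises if any between-factor
    cell holds fewer than 2 subjects.
    """
    within = list(within)
    between = list(between)
    cols = [subject] + between + within + [dv]
    d = data[cols].dropna()

    # one row per subject x within-cell; pivot to wide
    wide = d.pivot_table(index=[subject] + between, columns=within, values=dv, aggfunc="mean")
    n_cells = int(np.prod([d[w].nunique() for w in within])) if within else 1
    wide = wide.dropna()
    if within and wide.shape[1] != n_cells:
        raise ValueError("within-factor structure is not fully crossed")
    meta = wide.index.to_frame(index=False)
    if between:
        counts = meta.groupby(between, observed=True).size()
        if (counts < 2).any():
            raise ValueError("each between-subject cell needs at least 2 subjects")
    Y = wide.to_numpy()
    n = Y.shape[0]

    # within contrast bases, ordered to match the pivot's column product
    if within:
        if len(within) > 1:
            level_sets = [list(wide.columns.get_level_values(i).unique()) for i in range(len(within))]
        else:
            level_sets = [list(wide.columns)]
        bases = {w: _orthonormal_contrasts(len(levels)) for w, levels in zip(within, level_sets)}
        within_effects = []
        for r in range(len(within) + 1):
            for S in itertools.combinations(within, r):
                C = np.ones((1, 1))
                for w in within:
                    mean_b, con_b = bases[w]
                    C = np.kron(C, con_b if w in S else mean_b)
                within_effects.append((S, C))
    else:
        within_effects = [((), np.ones((1, 1)))]

    # between design: intercept + effect-coded terms (all subsets)
    codes = {b: _effect_code(meta[b])[0] for b in between}
    terms: list[tuple[tuple[str, ...], np.ndarray]] = [((), np.ones((n, 1)))]
    for r in range(1, len(between) + 1):
        for T in itertools.combinations(between, r):
            X = np.ones((n, 1))
            for b in T:
                X = _interact(X, codes[b])
            terms.append((T, X))
    X_full = np.hstack([X for _, X in terms])
    offsets = np.cumsum([0] + [X.shape[1] for _, X in terms])
    df_e = n - np.linalg.matrix_rank(X_full)
    if df_e <= 0:
        raise ValueError("no error degrees of freedom for the between design")

    rows = []
    y_scale = float(np.sum(Y * Y)) + 1.0
    for S, C in within_effects:
        q = C.shape[1]
        if q == 0:
            continue
        U = Y @ C
        # a stratum with (numerically) no variation at all: F = 0 by convention
        degenerate = float(np.sum(U * U)) <= y_scale * 1e-24
        sse_full = _sse(U, X_full)
        E = _error_cov(U, X_full)
        # Greenhouse-Geisser epsilon from the error covariance of the contrasts
        if q == 1:
            eps = 1.0
        else:
            Sg = E / df_e
            eps = float(np.trace(Sg) ** 2 / (q * np.trace(Sg @ Sg)))
            eps = min(max(eps, 1.0 / q), 1.0)
        for ti, (T, XT) in enumerate(terms):
            if not S and not T:
                continue  # grand mean: not an effect
            keep = np.ones(X_full.shape[1], dtype=bool)
            keep[offsets[ti] : offsets[ti + 1]] = False
            sse_red = _sse(U, X_full[:, keep])
            ss_h = sse_red - sse_full
            df_t = XT.shape[1]
            df_num = df_t * q
            df_den = df_e * q
            if degenerate:
                F, ss_h, sse_full_out = 0.0, 0.0, 0.0
            elif sse_full > 0:
                F = (ss_h / df_num) / (sse_full / df_den)
                sse_full_out = sse_full
            else:
                F, sse_full_out = np.inf, sse_full
            p = float(stats.f.sf(F, df_num, df_den)) if np.isfinite(F) else 0.0
            p_gg = float(stats.f.sf(F, df_num * eps, df_den * eps)) if np.isfinite(F) else 0.0
            name = ":".join(list(T) + list(S)) or "(grand mean)"
            rows.append(
                {
                    "effect": name,
                    "df_num": df_num,
                    "df_den": df_den,
                    "F": float(F),
                    "p": p,
                    "gg_epsilon": eps,
                    "p_gg": p_gg,
                    "ss_effect": ss_h,
                    "ss_error": sse_full_out,
                    "n_subjects": n,
                }
            )
    return pd.DataFrame(rows)


def _interact(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Column-wise interaction (row-wise Khatri-Rao product)."""
    n = A.shape[0]
    return (A[:, :, None] * B[:, None, :]).reshape(n, -1)
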