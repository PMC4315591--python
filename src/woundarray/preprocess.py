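"""Non-specific filtering, quantile normalization and probe-set summarization.

The preprocessing path is: linear-scale intensity filter → log2 transform →
between-array quantile normalization → median-polish summarization of
probe sets.  Boundary conventions (strict ``>`` for the intensity cut,
``>=`` for the sample fraction, strict ``>`` for the IQR percentile) are
configurable through the operation parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ExpressionMatrix, ValidationError


@dataclass
class FilterResult:
    matrix: ExpressionMatrix
    n_kept: int
    n_removed: int


def nonspecific_filter(
    m: ExpressionMatrix,
    min_intensity: float = 40.0,
    min_frac: float = 0.25,
    iqr_percentile: float = 10.0,
) -> FilterResult:
    """Drop low-signal and low-variability rows from a linear-scale matrix.

    A row is kept iff (a) the fraction of samples with intensity strictly
    greater than ``min_intensity`` is at least ``min_frac`` and (b) its
    inter-quartile range is strictly greater than the ``iqr_percentile``-th
    percentile of the distribution of row IQRs.
    """
    if m.scale != "linear":
        raise ValidationError("nonspecific_filter requires linear-scale input")
    x = m.values.to_numpy(dtype=float)
    frac_bright = (x > min_intensity).mean(axis=1)
    q75, q25 = np.percentile(x, [75, 25], axis=1)
    iqr = q75 - q25
    iqr_cut = np.percentile(iqr, iqr_percentile)
    keep = (frac_bright >= min_frac) & (iqr > iqr_cut)
    kept = m.values.loc[keep]
    return FilterResult(
        matrix=ExpressionMatrix(kept, scale="linear"),
        n_kept=int(keep.sum()),
        n_removed=int((~keep).sum()),
    )


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Between-array quantile normalization.

    Each column's sorted values are replaced by the across-column mean of
    sorted values; tied entries within a column receive the mean of the
    reference values their positions span.  Single-column input is returned
    unchanged.
    """
    x = m.values.to_numpy(dtype=float)
    n_genes, n_samples = x.shape
    if n_samples < 2:
        return m
    order = np.argsort(x, axis=0, kind="stable")
    reference = np.mean(np.take_along_axis(x, order, axis=0), axis=1)
    out = np.empty_like(x)
    for j in range(n_samples):
        col = x[:, j]
        idx = order[:, j]
        normed = np.empty(n_genes)
        normed[idx] = reference
        # tied input values get the mean of their assigned reference values
        sorted_col = col[idx]
        start = 0
        while start < n_genes:
            stop = start
            while stop + 1 < n_genes and sorted_col[stop + 1] == sorted_col[start]:
                stop += 1
            if stop > start:
                normed[idx[start : stop + 1]] = reference[start : stop + 1].mean()
            start = stop + 1
        out[:, j] = normed
    return ExpressionMatrix(
        pd.DataFrame(out, index=m.values.index, columns=m.values.columns),
        scale=m.scale,
    )


def median_polish(
    x: np.ndarray, tol: float = 1e-6, max_iter: int = 10
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Tukey median polish of a 2-D array.

    Returns ``(overall, row_effects, col_effects, residuals)`` with
    ``x ≈ overall + row[:, None] + col[None, :] + residuals``.
    """
    resid = np.asarray(x, dtype=float).copy()
    overall = 0.0
    row = np.zeros(resid.shape[0])
    col = np.zeros(resid.shape[1])
    last = np.abs(resid).sum()
    for _ in range(max_iter):
        rmed = np.median(resid, axis=1)
        row += rmed
        resid -= rmed[:, None]
        cmed = np.median(row)
        overall += cmed
        row -= cmed
        ccol = np.median(resid, axis=0)
        col += ccol
        resid -= ccol[None, :]
        rshift = np.median(col)
        overall += rshift
        col -= rshift
        total = np.abs(resid).sum()
        if last - total < tol * max(last, 1.0):
            break
        last = total
    return overall, row, col, resid


def summarize_probesets(
    m: ExpressionMatrix,
    probe_to_set: dict[str, str] | list[tuple[str, str]],
) -> ExpressionMatrix:
    """Collapse probes to probe-set signals by median polish.

    The summarized value for a set × sample cell is the polish's overall
    effect plus that sample's column effect.  Singleton sets pass through
    unchanged.  Every probe must map to exactly one set.
    """
    if m.scale != "log2":
        raise ValidationError("summarize_probesets expects log2-scale input")
    if not isinstance(probe_to_set, dict):
        mapping: dict[str, str] = {}
        for probe, ps in probe_to_set:
            if probe in mapping and mapping[probe] != ps:
                raise ValidationError(f"probe {probe!r} maps to two probe sets")
            mapping[probe] = ps
        probe_to_set = mapping
    sets: dict[str, list[str]] = {}
    for probe in m.values.index:
        ps = probe_to_set.get(probe)
        if ps is None:
            raise ValidationError(f"probe {probe!r} has no probe-set mapping")
        sets.setdefault(ps, []).append(probe)
    rows = {}
    for ps, probes in sets.items():
        sub = m.values.loc[probes].to_numpy(dtype=float)
        if len(probes) == 1:
            rows[ps] = sub[0]
        else:
            overall, _, col, _ = median_polish(sub)
            rows[ps] = overall + col
    out = pd.DataFrame.from_dict(rows, orient="index", columns=m.values.columns)
    out = out.loc[sorted(rows)]
    return ExpressionMatrix(out, scale="log2")
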