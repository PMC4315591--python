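"""Template-matching clustering of four-condition expression profiles.

Condition means are discretized to three levels (1 = low, 2 = medium,
3 = high) by per-gene min-max scaling into equal thirds; genes whose
profile range is below ``flat_eps`` log2 units are flagged flat.  Each
non-flat gene is matched by squared Pearson correlation against the 81
level templates (the 3 constant templates are degenerate and excluded) and
assigned to the best template when R² exceeds the threshold.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ValidationError


@dataclass(frozen=True)
class TemplateProfile:
    levels: tuple[int, ...]

    @property
    def id(self) -> str:
        return ".".join(str(v) for v in self.levels)

    @property
    def degenerate(self) -> bool:
        return len(set(self.levels)) == 1


def enumerate_templates(levels: int = 3, n_conditions: int = 4) -> list[TemplateProfile]:
    """All levels^n_conditions profiles in lexicographic order."""
    if levels < 2 or n_conditions < 1:
        raise ValidationError("need levels ≥ 2 and n_conditions ≥ 1")
    return [
        TemplateProfile(tuple(combo))
        for combo in itertools.product(range(1, levels + 1), repeat=n_conditions)
    ]


def prefilter_for_templates(
    tables: dict[str, pd.DataFrame], alpha: float = 0.05
) -> pd.Index:
    """Genes with BH-adjusted p < alpha in at least one of W, NW, D."""
    for key in ("W", "NW", "D"):
        if key not in tables:
            raise ValidationError(f"missing contrast table {key!r}")
    genes = tables["W"].index
    mask = np.zeros(len(genes), dtype=bool)
    for key in ("W", "NW", "D"):
        mask |= (tables[key]["p_adj"] < alpha).to_numpy()
    return genes[mask]


def discretize_profile(
    condition_means: np.ndarray, flat_eps: float = 0.5
) -> tuple[int, ...] | None:
    """Min-max scale a 4-value profile to [0,1] and bin into thirds.

    Returns ``None`` (flat flag) when max − min < flat_eps.  Bins are
    half-open: [0, 1/3) → 1, [1/3, 2/3) → 2, [2/3, 1] → 3.
    """
    x = np.asarray(condition_means, dtype=float)
    if not np.isfinite(x).all():
        raise ValidationError("non-finite values in condition means")
    span = x.max() - x.min()
    if span < flat_eps:
        return None
    scaled = (x - x.min()) / span
    levels = np.where(scaled < 1.0 / 3.0, 1, np.where(scaled < 2.0 / 3.0, 2, 3))
    return tuple(int(v) for v in levels)


def _r_squared(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt(float(xc @ xc) * float(yc @ yc))
    if denom == 0.0:
        return float("nan")
    r = float(xc @ yc) / denom
    return r * r


def match_templates(
    profile: np.ndarray,
    templates: list[TemplateProfile] | None = None,
    r2_threshold: float = 0.95,
    replicate_counts: list[int] | None = None,
) -> tuple[str | None, float]:
    """Best-template assignment for one gene profile.

    ``profile`` is either the 4 condition means or, in replicate mode, the
    concatenated replicate values with ``replicate_counts`` giving how many
    replicates each condition contributes (templates are expanded to match).
    Returns ``(template_id or None, best R²)``; ties go to the smallest id.
    """
    x = np.asarray(profile, dtype=float)
    if np.ptp(x) == 0.0:
        raise ValidationError("zero-variance profile; flat-flag it upstream")
    if templates is None:
        templates = enumerate_templates()
    best_id, best_r2 = None, -1.0
    for tpl in sorted(templates, key=lambda t: t.id):
        if tpl.degenerate:
            continue
        y = np.asarray(tpl.levels, dtype=float)
        if replicate_counts is not None:
            y = np.repeat(y, replicate_counts)
        r2 = _r_squared(x, y)
        if np.isnan(r2):
            continue
        if r2 > best_r2 + 1e-12:
            best_id, best_r2 = tpl.id, r2
    if best_r2 > r2_threshold:
        return best_id, best_r2
    return None, best_r2


def assign_clusters(
    condition_means: pd.DataFrame,
    genes: pd.Index | None = None,
    r2_threshold: float = 0.95,
    flat_eps: float = 0.5,
    replicate_values: pd.DataFrame | None = None,
    replicate_counts: list[int] | None = None,
) -> pd.DataFrame:
    """Template assignment table for a set of genes.

    Columns: ``flat`` flag, ``levels`` ("a.b.c.d" or ""), ``template``
    (best id or ""), ``r2``.  With ``replicate_values`` the correlation is
    computed against replicate-expanded templates (12 vs 12) instead of the
    4 condition means.
    """
    if genes is None:
        genes = condition_means.index
    templates = enumerate_templates()
    rows = []
    for gene in genes:
        means = condition_means.loc[gene].to_numpy(dtype=float)
        levels = discretize_profile(means, flat_eps=flat_eps)
        if levels is None:
            rows.append((gene, True, "", "", float("nan")))
            continue
        if replicate_values is not None:
            prof = replicate_values.loc[gene].to_numpy(dtype=float)
            tid, r2 = match_templates(
                prof, templates, r2_threshold, replicate_counts=replicate_counts
            )
        else:
            tid, r2 = match_templates(means, templates, r2_threshold)
        rows.append(
            (gene, False, ".".join(map(str, levels)), tid or "", r2)
        )
    out = pd.DataFrame(
        rows, columns=["gene", "flat", "levels", "template", "r2"]
    ).set_index("gene")
    return out
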