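"""Multi-contrast set logic: Venn regions, WO / W-NW-D sets, sign subsets.

Membership in the W, NW and D populations comes from thresholded contrast
tables; combining the three boolean flags yields the 7 non-empty Venn
regions.  Two composite sets are singled out: WO (in W and D but not NW —
wounded-only response) and W/NW/D (in all three — shared but distinct
response).  Genes in those sets are further classified by the qualitative
sign pattern of within-population (wounded vs non-wounded) changes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ValidationError
from .differential import select_genes

VENN_REGIONS = (
    "W",
    "NW",
    "D",
    "W∩NW",
    "W∩D",
    "NW∩D",
    "W∩NW∩D",
)

WO_SIMPLE_SUBSETS = (
    "WO:JNK+_up",  # upregulated in JNK+ W cells only
    "WO:JNK-_down",  # downregulated in JNK- W cells only
    "WO:JNK+_down",  # downregulated in JNK+ W cells only
    "WO:JNK-_up",  # upregulated in JNK- W cells only
)

# Autonomous W/NW/D subsets: change in the JNK+ population only, labelled by
# the signs of the W and NW differentials and, when equal, their magnitude
# order (wounded change larger vs non-wounded change larger).
WNWD_AUTONOMOUS_SUBSETS = (
    "WNWD:auto_up_more_W",
    "WNWD:auto_up_more_NW",
    "WNWD:auto_down_more_W",
    "WNWD:auto_down_more_NW",
    "WNWD:auto_up_W_down_NW",
    "WNWD:auto_down_W_up_NW",
)

WNWD_NONAUTONOMOUS_SUBSETS = tuple(
    s.replace("auto", "nonauto") for s in WNWD_AUTONOMOUS_SUBSETS
)


def region_label(in_w: bool, in_nw: bool, in_d: bool) -> str:
    """Venn region label from the three membership flags."""
    parts = [name for flag, name in ((in_w, "W"), (in_nw, "NW"), (in_d, "D")) if flag]
    return "∩".join(parts) if parts else "none"


def build_membership(
    tables: dict[str, pd.DataFrame],
    fc_cut: float = 1.3,
    alpha: float = 0.05,
    use_adjusted: bool = True,
) -> pd.DataFrame:
    """Per-gene membership flags and Venn region over contrasts W, NW, D."""
    for key in ("W", "NW", "D"):
        if key not in tables:
            raise ValidationError(f"missing contrast table {key!r}")
    genes = tables["W"].index
    for key in ("NW", "D"):
        if not genes.equals(tables[key].index):
            raise ValidationError("contrast tables have mismatched gene universes")
    flags = {}
    for key in ("W", "NW", "D"):
        sel = select_genes(tables[key], fc_cut, alpha, use_adjusted=use_adjusted)
        flags[f"in{key}"] = genes.isin(sel.index)
    out = pd.DataFrame(flags, index=genes)
    out["venn_region"] = [
        region_label(w, nw, d)
        for w, nw, d in zip(out["inW"], out["inNW"], out["inD"])
    ]
    out.index.name = "gene"
    return out


def extract_sets(membership: pd.DataFrame) -> tuple[pd.Index, pd.Index]:
    """Return (WO, W/NW/D) gene index pair; disjoint by construction."""
    wo = membership.index[
        membership["inW"] & membership["inD"] & ~membership["inNW"]
    ]
    wnwd = membership.index[
        membership["inW"] & membership["inNW"] & membership["inD"]
    ]
    return wo, wnwd


@dataclass
class SignPattern:
    """Qualitative per-gene changes; 0 means no significant change.

    ``d_jnk_pos`` / ``d_jnk_neg``: wounded-vs-non-wounded change within the
    JNK+ / JNK- population.  ``w_diff`` / ``nw_diff``: JNK+ vs JNK- within
    wounded / non-wounded discs.  ``w_larger``: |W effect| > |NW effect|
    (meaningful when both differentials share a sign).
    """

    d_jnk_pos: int
    d_jnk_neg: int
    w_diff: int
    nw_diff: int
    w_larger: bool


def sign_patterns(
    tables: dict[str, pd.DataFrame],
    fc_cut: float = 1.3,
    alpha: float = 0.05,
    use_adjusted: bool = True,
) -> pd.DataFrame:
    """Compute thresholded sign patterns from the five contrast tables.

    Requires contrasts W, NW, dJNK+ and dJNK- (the per-population wounded
    vs non-wounded comparisons).  A sign is declared only when the contrast
    passes the same FC/alpha rule used for set membership.
    """
    needed = ("W", "NW", "dJNK+", "dJNK-")
    for key in needed:
        if key not in tables:
            raise ValidationError(f"missing contrast table {key!r}")
    genes = tables["W"].index

    def signed(key: str) -> np.ndarray:
        sel = select_genes(tables[key], fc_cut, alpha, use_adjusted=use_adjusted)
        s = pd.Series(0, index=genes, dtype=int)
        s.loc[sel.index[sel["direction"] == "up"]] = 1
        s.loc[sel.index[sel["direction"] == "down"]] = -1
        return s.to_numpy()

    out = pd.DataFrame(
        {
            "d_jnk_pos": signed("dJNK+"),
            "d_jnk_neg": signed("dJNK-"),
            "w_diff": signed("W"),
            "nw_diff": signed("NW"),
            "w_larger": tables["W"]["beta"].abs().to_numpy()
            > tables["NW"]["beta"].abs().to_numpy(),
        },
        index=genes,
    )
    out.index.name = "gene"
    return out


def _classify_wo(row: pd.Series) -> str:
    dp, dn = int(row["d_jnk_pos"]), int(row["d_jnk_neg"])
    if dp == 1 and dn == 0:
        return "WO:JNK+_up"
    if dp == 0 and dn == -1:
        return "WO:JNK-_down"
    if dp == -1 and dn == 0:
        return "WO:JNK+_down"
    if dp == 0 and dn == 1:
        return "WO:JNK-_up"
    if dp != 0 and dn != 0:
        return f"WO:complex_{'+' if dp > 0 else '-'}{'+' if dn > 0 else '-'}"
    return "WO:other"


def _classify_wnwd(row: pd.Series) -> str:
    dp, dn = int(row["d_jnk_pos"]), int(row["d_jnk_neg"])
    w, nw = int(row["w_diff"]), int(row["nw_diff"])
    if dp != 0 and dn != 0:
        return f"WNWD:complex_{'+' if dp > 0 else '-'}{'+' if dn > 0 else '-'}"
    if dp == 0 and dn == 0:
        return "WNWD:other"
    prefix = "auto" if dp != 0 else "nonauto"
    if w == 1 and nw == 1:
        tag = "up_more_W" if row["w_larger"] else "up_more_NW"
    elif w == -1 and nw == -1:
        tag = "down_more_W" if row["w_larger"] else "down_more_NW"
    elif w == 1 and nw == -1:
        tag = "up_W_down_NW"
    elif w == -1 and nw == 1:
        tag = "down_W_up_NW"
    else:
        return "WNWD:other"
    return f"WNWD:{prefix}_{tag}"


def classify_subsets(
    membership: pd.DataFrame, signs: pd.DataFrame
) -> pd.DataFrame:
    """Assign every WO / W-NW-D gene exactly one subset label."""
    wo, wnwd = extract_sets(membership)
    rows = []
    for gene in wo:
        rows.append((gene, "WO", _classify_wo(signs.loc[gene])))
    for gene in wnwd:
        rows.append((gene, "WNWD", _classify_wnwd(signs.loc[gene])))
    out = pd.DataFrame(rows, columns=["gene", "set", "subset"]).set_index("gene")
    return out


def classify_gene(membership_row: pd.Series, sign_row: pd.Series) -> str:
    """Subset label for one gene; rejects genes outside WO and W/NW/D."""
    in_wo = (
        membership_row["inW"] and membership_row["inD"] and not membership_row["inNW"]
    )
    in_wnwd = (
        membership_row["inW"] and membership_row["inNW"] and membership_row["inD"]
    )
    if in_wo:
        return _classify_wo(sign_row)
    if in_wnwd:
        return _classify_wnwd(sign_row)
    raise ValidationError("gene belongs to neither the WO nor the W/NW/D set")


def enumerate_subset_space(set_name: str) -> list[str]:
    """Admissible qualitative pattern codes for a named set."""
    if set_name == "WO-simple":
        return list(WO_SIMPLE_SUBSETS)
    if set_name == "WNWD-autonomous":
        return list(WNWD_AUTONOMOUS_SUBSETS)
    if set_name == "WNWD-nonautonomous":
        return list(WNWD_NONAUTONOMOUS_SUBSETS)
    if set_name == "venn-regions":
        return list(VENN_REGIONS)
    if set_name == "templates":
        return [
            ".".join(str(v) for v in combo)
            for combo in itertools.product((1, 2, 3), repeat=4)
        ]
    raise ValidationError(f"unknown set name {set_name!r}")
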