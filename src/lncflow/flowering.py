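"""Antagonistic flowering-regulator calls from the two-comparison DE pattern.

Under a short-day / night-break design a lncRNA that rises with progressing
short days (up in SD1_vs_SD2) and falls after the night break (down in
SD2_vs_NB) is called a putative *positive* flowering regulator; the mirrored
pattern is a *negative* regulator. lncRNAs responding in only one
comparison, or in the same direction in both, are labelled ``none``.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd


@dataclass(frozen=True)
class FloweringCall:
    lncrna_id: str
    label: str
    dir_sd: str
    dir_nb: str


def _direction_map(de: pd.DataFrame) -> dict[str, str]:
    dup = de["feature_id"].duplicated()
    if dup.any():
        ids = sorted(de.loc[dup, "feature_id"].unique().tolist())
        raise ValueError(f"duplicate DE rows for features {ids[:5]}")
    return dict(zip(de["feature_id"], de["direction"]))


def call_flowering(
    de_sd: pd.DataFrame, de_nb: pd.DataFrame
) -> list[FloweringCall]:
    """Label every lncRNA in the union of both DE tables.

    ``de_sd`` is the SD1_vs_SD2 result and ``de_nb`` the SD2_vs_NB result
    (any feature kind is accepted; pass lncRNA rows only for regulator calls).
    """
    dirs_sd = _direction_map(de_sd)
    dirs_nb = _direction_map(de_nb)
    calls = []
    for lnc in sorted(set(dirs_sd) | set(dirs_nb)):
        d_sd = dirs_sd.get(lnc, "ns")
        d_nb = dirs_nb.get(lnc, "ns")
        if d_sd == "up" and d_nb == "down":
            label = "positive"
        elif d_sd == "down" and d_nb == "up":
            label = "negative"
        else:
            label = "none"
        calls.append(FloweringCall(lnc, label, d_sd, d_nb))
    return calls


def calls_to_frame(calls: list[FloweringCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"lncrna_id": c.lncrna_id, "label": c.label,
             "dir_sd": c.dir_sd, "dir_nb": c.dir_nb}
            for c in calls
        ],
        columns=["lncrna_id", "label", "dir_sd", "dir_nb"],
    )


def venn_census(
    dirs_sd: Mapping[str, str], dirs_nb: Mapping[str, str]
) -> dict[str, int]:
    """Two-set census of the DE sets plus the opposite-direction overlap.

    Inputs map DE feature ids to their direction (``up``/``down``) in each
    comparison; ids present in a mapping constitute that comparison's DE set.
    """
    set_sd = set(dirs_sd)
    set_nb = set(dirs_nb)
    both = set_sd & set_nb
    opposite = sum(
        1
        for f in both
        if {dirs_sd[f], dirs_nb[f]} == {"up", "down"}
    )
    return {
        "n_sd_only": len(set_sd - set_nb),
        "n_nb_only": len(set_nb - set_sd),
        "n_both": len(both),
        "n_union": len(set_sd | set_nb),
        "n_opposite": opposite,
    }


def de_direction_map(de: pd.DataFrame) -> dict[str, str]:
    """Significant features of a DE table mapped to their direction."""
    sig = de[de["direction"].isin(["up", "down"])]
    return _direction_map(sig)
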