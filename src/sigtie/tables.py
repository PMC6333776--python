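"""Tabular (TSV) emission and re-parsing of filter outputs."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd

from .activity import ActivityVector
from .baselines import DisparityBackbone
from .significance import TriadTest

__all__ = [
    "backbone_frame",
    "write_backbone",
    "read_backbone",
    "triad_frame",
    "write_triads",
    "write_activities",
    "read_activities",
]


def backbone_frame(backbone, method: str = "ST") -> pd.DataFrame:
    """One row per tested pair: ``i j m_obs u p_value significant method``.

    Accepts an ST :class:`Backbone` or a :class:`DisparityBackbone` (whose
    rows carry the edge weight in ``m_obs`` and no null probability).
    """
    rows = []
    if isinstance(backbone, DisparityBackbone):
        kept = backbone.pairs
        for s in backbone.scores:
            rows.append(
                dict(i=s.pair[0], j=s.pair[1], m_obs=s.weight, u=float("nan"),
                     p_value=s.p_value, significant=s.pair in kept, method=method)
            )
    else:
        for t in backbone.tests:
            rows.append(
                dict(i=t.pair[0], j=t.pair[1], m_obs=t.m_obs, u=t.u,
                     p_value=t.p_value, significant=t.significant, method=method)
            )
    return pd.DataFrame(rows, columns=["i", "j", "m_obs", "u", "p_value",
                                       "significant", "method"])


def write_backbone(backbone, path, method: str = "ST") -> None:
    backbone_frame(backbone, method=method).to_csv(path, sep="\t", index=False)


def read_backbone(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def triad_frame(triads: Sequence[TriadTest]) -> pd.DataFrame:
    rows = [
        dict(i=t.triple[0], j=t.triple[1], k=t.triple[2], r_obs=t.r_obs, v=t.v,
             p_value=t.p_value, significant=t.significant,
             n_sig_dyads=t.n_significant_dyads)
        for t in triads
    ]
    return pd.DataFrame(rows, columns=["i", "j", "k", "r_obs", "v", "p_value",
                                       "significant", "n_sig_dyads"])


def write_triads(triads: Sequence[TriadTest], path) -> None:
    triad_frame(triads).to_csv(path, sep="\t", index=False)


def write_activities(result: ActivityVector, path, sidecar=None) -> None:
    """``node<TAB>activity`` table plus an optional JSON diagnostics sidecar."""
    with Path(path).open("w") as fh:
        fh.write("node\tactivity\n")
        for node, a in result.activities.items():
            fh.write(f"{node}\t{a:.12g}\n")
    if sidecar is not None:
        diag = dict(
            converged=result.converged,
            residual_norm=result.residual_norm,
            iterations=result.iterations,
            projected=[repr(n) for n in result.projected],
            excluded=[repr(n) for n in result.excluded],
        )
        Path(sidecar).write_text(json.dumps(diag, indent=2))


def read_activities(path) -> dict:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["node"], df["activity"]))
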