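"""Order/disorder and mobility summaries from structure confidence tracks.

Predicted models carry pLDDT in the B-factor column; residues with pLDDT
strictly above 70 (on the 0–100 scale) count as ordered.  Experimental
structures contribute crystallographic B-factors (Å²), summarised per
protein by the median.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .constraint import assign_deciles
from .formats_io import GeneAnnotation, StructureConfidence

logger = logging.getLogger("mutstab")

PLDDT_CUTOFF = 70.0

LOEUF_GROUPS = {**{d: "Most" for d in (0, 1, 2)},
                **{d: "Intermediate" for d in (3, 4, 5, 6)},
                **{d: "Least" for d in (7, 8, 9)}}
GROUPINGS = ("loeuf_decile_grouped", "shet_category", "pli_binary")


def ordered_fraction(conf: StructureConfidence, cutoff: float = PLDDT_CUTOFF) -> float:
    """Fraction of residues with pLDDT strictly above ``cutoff``.

    Values on a 0–1 scale (maximum <= 1) are rescaled to 0–100 first, so
    both conventions for storing pLDDT are accepted.
    """
    if conf.source_kind != "predicted_model":
        raise ValueError("ordered_fraction expects a predicted model (pLDDT track)")
    values = np.asarray(conf.values, dtype=float)
    if values.size == 0:
        raise ValueError("empty residue list")
    if values.max() <= 1.0:
        values = values * 100.0
    return float((values > cutoff).mean())


def median_bfactor(conf: StructureConfidence) -> float:
    """Median per-residue B-factor of an experimental structure (Å²).

    Even residue counts average the two central order statistics.
    """
    if conf.source_kind != "experimental":
        raise ValueError("median_bfactor expects an experimental structure")
    if len(conf) == 0:
        raise ValueError("empty residue list")
    return float(np.median(conf.values))


def grouped_metric_table(
    per_gene: Mapping[str, float] | pd.Series,
    annotations: Iterable[GeneAnnotation],
    grouping: str,
) -> pd.DataFrame:
    """Per-group summary (median, quartiles, n) of a per-gene metric.

    Groupings: ``loeuf_decile_grouped`` bins published LOEUF into deciles
    and maps bins 0–2 to Most, 3–6 to Intermediate, 7–9 to Least
    constrained; ``shet_category`` uses the annotation's category;
    ``pli_binary`` splits at pLi 0.5 (low: pLi < 0.5, high: pLi >= 0.5).
    Genes that cannot be resolved to a group are dropped and tallied in
    ``df.attrs['n_dropped']``; empty groups appear with n=0 and missing
    summaries.
    """
    if grouping not in GROUPINGS:
        raise ValueError(f"unknown grouping {grouping!r}")
    values = pd.Series(dict(per_gene)) if not isinstance(per_gene, pd.Series) else per_gene
    ann = {a.gene_id: a for a in annotations}

    if grouping == "loeuf_decile_grouped":
        loeuf = {
            g: a.loeuf_published for g, a in ann.items() if a.loeuf_published is not None
        }
        deciles = assign_deciles(pd.Series(loeuf))
        group_of = {g: LOEUF_GROUPS[int(d)] for g, d in deciles.items()}
        group_order = ["Most", "Intermediate", "Least"]
    elif grouping == "shet_category":
        group_of = {g: a.shet_category for g, a in ann.items() if a.shet_category}
        group_order = ["extreme", "strong", "weak", "neutral"]
    else:
        group_of = {
            g: ("low" if a.pli < 0.5 else "high")
            for g, a in ann.items()
            if a.pli is not None
        }
        group_order = ["low", "high"]

    n_dropped = sum(1 for g in values.index if g not in group_of)
    if n_dropped:
        logger.info("grouped_metric_table: dropped %d unresolvable genes", n_dropped)

    rows = []
    for group in group_order:
        members = values[[g for g in values.index if group_of.get(g) == group]]
        if len(members):
            q1, med, q3 = np.quantile(members, [0.25, 0.5, 0.75], method="linear")
        else:
            q1 = med = q3 = np.nan
        rows.append(
            {"group": group, "n": int(len(members)), "median": med, "q1": q1, "q3": q3}
        )
    df = pd.DataFrame(rows)
    df.attrs["n_dropped"] = n_dropped
    return df
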