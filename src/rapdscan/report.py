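"""Summary views assembled from the core tables.

Three views mirror the tool's purpose: which primers prime more than
once in a sequence (multi-site), which primers have an amplifiable
product (shortlist), and how sites distribute over sequence libraries
(tally).  Every summary row is re-derivable from the core tables; the
builder cross-checks its inputs and refuses inconsistent ones.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .amplicon import AmpliconPrediction, Shortlist
from .sitescan import SiteTable, site_frequency


@dataclass(frozen=True)
class SummaryView:
    """A named tabular summary plus where it was derived from."""

    name: str
    frame: pd.DataFrame
    provenance: str


def build_summaries(
    sites: SiteTable,
    amplicons: Sequence[AmpliconPrediction],
    shortlist: Shortlist,
    tallies: pd.DataFrame,
) -> list[SummaryView]:
    """Build the multi-site, shortlist and library-tally views.

    All inputs must come from one run: an amplicon referencing a site
    absent from the SiteTable is a hard error.  The multi-site
    threshold is fixed at two sites — a primer priming once cannot
    delimit a product.
    """
    site_keys = {s.key for s in sites}
    for pred in amplicons:
        for site in (pred.left_site, pred.right_site):
            if site.key not in site_keys:
                raise ValueError(
                    f"amplicon for {pred.primer_name!r} in {pred.sequence_id!r} "
                    f"references a site absent from the site table: {site.key}"
                )

    freq = site_frequency(sites)
    multi = (
        freq.loc[freq["multi_site"], ["primer_name", "sequence_id", "n_sites"]]
        .reset_index(drop=True)
        if len(freq)
        else pd.DataFrame(columns=["primer_name", "sequence_id", "n_sites"])
    )

    shortlist_rows = [
        {
            "primer_name": e.primer_name,
            "n_in_window_pairs": e.n_in_window_pairs,
            "best_sequence_id": e.best.sequence_id,
            "best_product_size": e.best.product_size,
        }
        for e in shortlist
    ]
    shortlist_df = pd.DataFrame(
        shortlist_rows,
        columns=[
            "primer_name",
            "n_in_window_pairs",
            "best_sequence_id",
            "best_product_size",
        ],
    )

    return [
        SummaryView(
            name="multisite",
            frame=multi,
            provenance="site_frequency filtered to n_sites >= 2",
        ),
        SummaryView(
            name="shortlist",
            frame=shortlist_df,
            provenance="shortlist_primers over in-window amplicon predictions",
        ),
        SummaryView(
            name="library_tally",
            frame=tallies.reset_index(drop=True),
            provenance="tally_by_library over the site table",
        ),
    ]
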