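"""Gene-set overrepresentation analysis (ORA).

Hypergeometric enrichment of a query gene list in predefined gene-set
libraries against a background universe — here, the background is all
genes overlapped by at least one CNV in at least one sample, and the
query is the subset showing disease association.

For a set with K of its members in the background (size N) and a query of
size n with k hits, the one-sided enrichment p is the hypergeometric upper
tail P(X >= k). Benjamini-Hochberg correction is applied *within each
library* separately. Reported sets additionally require at least
``min_overlap`` query hits.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import pandas as pd
from scipy.stats import hypergeom

from .exact import bh_adjust, fisher_p_two_sided
from .io import GeneSetLibrary, ValidationError

logger = logging.getLogger(__name__)

__all__ = ["run_ora"]

ORA_COLUMNS = [
    "library_name", "set_id", "description", "hits", "set_in_background",
    "query_size", "background_size", "p", "p_adj", "reported", "member_hits",
]


def run_ora(
    query_genes: Iterable[str],
    background_genes: Iterable[str],
    libraries: Sequence[GeneSetLibrary],
    p_adj_threshold: float = 0.25,
    min_overlap: int = 2,
    two_sided: bool = False,
) -> pd.DataFrame:
    """Enrichment of ``query_genes`` within each library's sets.

    Query genes outside the background are dropped with a warning (the
    test is conditional on the background universe). Set membership is
    likewise intersected with the background. ``two_sided`` switches from
    the upper-tail hypergeometric to the two-tailed Fisher convention.

    Returns one row per (library, set), sorted by library then p, with
    ``reported`` flagging sets that satisfy both the ``min_overlap`` and
    the within-library BH threshold.
    """
    background = set(background_genes)
    if not background:
        raise ValidationError("ORA background is empty")
    query = set(query_genes)
    outside = query - background
    if outside:
        logger.warning("ORA: dropping %d query gene(s) outside the background", len(outside))
        query &= background
    N, n = len(background), len(query)

    frames = []
    for lib in libraries:
        rows = []
        for set_id, (desc, members) in lib.sets.items():
            in_bg = set(members) & background
            K = len(in_bg)
            hit_genes = sorted(in_bg & query)
            k = len(hit_genes)
            if K == 0:
                p = 1.0
            elif two_sided:
                p = fisher_p_two_sided(k, n - k, K - k, N - K - (n - k))
            else:
                p = float(hypergeom.sf(k - 1, N, K, n))
            rows.append({
                "library_name": lib.library_name,
                "set_id": set_id,
                "description": desc,
                "hits": k,
                "set_in_background": K,
                "query_size": n,
                "background_size": N,
                "p": min(1.0, p),
                "member_hits": ",".join(hit_genes),
            })
        frame = pd.DataFrame(rows)
        if len(frame):
            frame["p_adj"] = bh_adjust(frame["p"].to_numpy())
            frame["reported"] = (frame["hits"] >= min_overlap) & \
                (frame["p_adj"] <= p_adj_threshold)
        frames.append(frame)
    if not frames:
        return pd.DataFrame(columns=ORA_COLUMNS)
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["library_name", "p", "set_id"],
                           kind="mergesort").reset_index(drop=True)[ORA_COLUMNS]
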