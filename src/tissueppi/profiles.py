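"""Cross-tissue expression profiling of interactor genes.

NX values are reported verbatim (no log transform or renormalisation) so
profile tables mirror the consensus expression resource exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix


def top_expressed(genes, matrix: ExpressionMatrix, tissue: str,
                  k: int) -> list[str]:
    """The k genes with the highest NX in a tissue, descending.

    Ties are broken alphabetically; genes with absent values rank last
    (alphabetically among themselves).  Requesting more genes than given
    returns the whole set, sorted.
    """
    genes = [g.upper() for g in genes]
    if not genes:
        raise ValueError("empty gene set")
    if k < 1:
        raise ValueError("k must be >= 1")
    if tissue not in matrix.tissues:
        raise KeyError(
            f"unknown tissue {tissue!r}; available: {', '.join(matrix.tissues)}"
        )

    def sort_key(g: str):
        v = matrix.value(g, tissue)
        return (v is None, -v if v is not None else 0.0, g)

    return sorted(dict.fromkeys(genes), key=sort_key)[:k]


def profile_table(genes, matrix: ExpressionMatrix,
                  tissues) -> pd.DataFrame:
    """Gene x tissue table of NX values; absent cells are NaN.

    Row order follows the input gene order; every non-absent cell equals
    the matrix entry exactly.
    """
    genes = list(dict.fromkeys(g.upper() for g in genes))
    tissues = list(tissues)
    unknown = [t for t in tissues if t not in matrix.tissues]
    if unknown:
        raise KeyError(
            f"unknown tissues {unknown}; available: {', '.join(matrix.tissues)}"
        )
    data = {
        t: [matrix.value(g, t) if matrix.value(g, t) is not None else np.nan
            for g in genes]
        for t in tissues
    }
    return pd.DataFrame(data, index=genes, columns=tissues)
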