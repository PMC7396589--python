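"""Bundled example tables.

``discovery_top7_de.tsv`` is the published per-method differential-expression
summary of the seven most dysregulated serum-exosome miRNAs from a mouse
Sjögren's-syndrome-model discovery cohort (NOD vs. BALB/c, 5 pooled samples
per strain): log2 fold changes with adjusted p-values for two methods
(deseq2, limma) and raw p-values for a third (edger, whose FDR column was not
published — its rows therefore carry no ``padj`` and can never support a
consensus hit here).  One method/feature combination (limma, miR-329-5p) was
not reported and is absent.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def example_serum_exosome_de() -> pd.DataFrame:
    """The seven-miRNA worked-example DE table (long format, one row per
    feature x method)."""
    ref = resources.files("srnagrep") / "data" / "discovery_top7_de.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")
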