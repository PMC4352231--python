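"""Bundled small datasets.

``load_kdr_allele_counts`` returns the published allele counts of the
L1014F and N1575Y kdr mutations in *Anopheles coluzzii* from Vallée du Kou
(VK7) and Tengrela, Burkina Faso, stratified by collection round and
deltamethrin exposure outcome, together with the frequencies and 95%
confidence intervals as printed in the original report (columns prefixed
``printed_``).  The printed values are carried for cross-checking only;
all statistics in this package are recomputed from the counts.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_kdr_allele_counts"]


def load_kdr_allele_counts() -> pd.DataFrame:
    with resources.files(__package__).joinpath("kdr_allele_counts.csv").open() as fh:
        return pd.read_csv(fh)
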