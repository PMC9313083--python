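"""Published reference numbers bundled with the package.

``data/winning_tf_counts.tsv`` holds the published per-group deregulation
counts of the 34 winning transcription factors from the three-cancer
meta-analysis this toolkit re-implements: for each TF, the number of lung
cancer (of 10), breast cancer (of 5) and leukemia (of 5) datasets in which it
was called deregulated. These counts are inputs for the descriptive
group-pattern categorization demo and for validation — the package never uses
them to fit anything.

``WINNING_DEG_SUMMARY`` holds the published headline counts of winning DEGs:
140 down- plus 156 up-regulated common winners, and 57 down- plus 41
up-regulated unique-lung-cancer winners.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: Published down/up counts of winning DEGs by category.
WINNING_DEG_SUMMARY = {
    "common": {"down": 140, "up": 156},
    "unique_lc": {"down": 57, "up": 41},
}


def load_winning_tf_counts() -> pd.DataFrame:
    """The 34 published winning-TF (lc, bc, lk) deregulation-count rows.

    Returns a DataFrame indexed by TF symbol with integer columns ``lc``,
    ``bc``, ``lk`` and a derived ``total``.
    """
    with resources.files("degnet.data").joinpath("winning_tf_counts.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", index_col="tf")
    df["total"] = df["lc"] + df["bc"] + df["lk"]
    return df
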