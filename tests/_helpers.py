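"""Shared builders for hand-made feature tables in tests."""

import numpy as np
import pandas as pd

from mucomet.tables import FeatureTable, GROUP, SAMPLE_ID


def make_table(values, state="raw", sample_ids=None, names=None) -> FeatureTable:
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    sample_ids = sample_ids or [f"S{i}" for i in range(1, n + 1)]
    names = names or [f"M{j}" for j in range(1, m + 1)]
    frame = pd.DataFrame(
        values, index=pd.Index(sample_ids, name=SAMPLE_ID), columns=names
    )
    return FeatureTable(frame, state=state)


def make_groups(table: FeatureTable, n_case: int, case="IBS", control="control"):
    labels = [case] * n_case + [control] * (table.n_samples - n_case)
    return pd.Series(labels, index=table.sample_ids, name=GROUP)
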