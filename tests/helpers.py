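import numpy as np
import pandas as pd


def toy_sample(y, psu=None, **extra) -> pd.DataFrame:
    """Small hand-built respondent frame for estimator arithmetic."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    df = pd.DataFrame({
        "cluster_id": np.arange(n) if psu is None else np.asarray(psu),
        "y": y,
    })
    for k, v in extra.items():
        df[k] = v
    return df
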