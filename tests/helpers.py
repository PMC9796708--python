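"""Small builders shared across test modules."""

import numpy as np

from kinectome.kinematics import AxisSeriesMatrix


def series_matrix(values, labels=None):
    values = np.asarray(values, dtype=float)
    labels = labels or tuple(f"M{i:02d}" for i in range(values.shape[1]))
    return AxisSeriesMatrix(
        quantity="acceleration", axis="ML", values=values,
        sampling_rate=120.0, labels=tuple(labels),
    )
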