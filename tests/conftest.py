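import numpy as np
import pytest

import impactsense as ims


@pytest.fixture(scope="session")
def personalized_study():
    """Standard synthetic personalized study: 1 subject x 8 sets, seed 0."""
    study, manifest = ims.generate_study(ims.personalized_spec(seed=0))
    return study, manifest


@pytest.fixture(scope="session")
def small_study():
    """A minimal study (1 subject x 1 set, 11 activities) for I/O and CLI."""
    study, manifest = ims.generate_study(
        ims.StudySpec(n_subjects=1, sets_per_subject=1, seed=7)
    )
    return study, manifest


def constant_ac_series(level, n=80, n_axes=1, t_s=27.5, axes=None):
    """Raw series whose DC-suppressed form has |a_AC| == level everywhere
    (alternating-sign construction: a = level * (-1)^k * ... cumulative)."""
    # a_AC[k] = (a[k] - a[k-1])/2; choose a alternating +-level so the
    # difference is -+2*level -> |a_AC| = level from sample 1 on
    base = level * ((-1.0) ** np.arange(n))
    data = np.tile(base[:, None], (1, n_axes))
    if axes is None:
        axes = ("x1", "y1", "y2", "x2")[:n_axes]
    return ims.AccelSeries(data, axes=axes, t_s=t_s)
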