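import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from scipy.stats import norm

from osteosex import FEMALE, MALE, GroupSummary, MeasurementRecord, StudyDataset

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


def grid_cutoff_oracle(
    female: GroupSummary, male: GroupSummary, coarse: float = 1e-3, fine: float = 1e-6
) -> float:
    """Brute-force sectioning-point oracle: grid scan of the D-value.

    Scans D(x) = F(x; female) − F(x; male) on the closed interval between the
    group means at a coarse step, then rescans a window around the coarse
    argmax at the fine step. The D-value is maximised at the density
    intersection whenever one lies between the means, so this scan is an
    independent check of the closed-form root selection.
    """
    lo, hi = sorted((female.mean, male.mean))
    xs = np.arange(lo, hi + coarse, coarse)
    xs = xs[xs <= hi]
    d = norm.cdf(xs, female.mean, female.sd) - norm.cdf(xs, male.mean, male.sd)
    centre = xs[int(np.argmax(np.abs(d)))]
    lo2, hi2 = max(lo, centre - 2 * coarse), min(hi, centre + 2 * coarse)
    xs2 = np.arange(lo2, hi2 + fine, fine)
    xs2 = xs2[xs2 <= hi]
    d2 = norm.cdf(xs2, female.mean, female.sd) - norm.cdf(xs2, male.mean, male.sd)
    return float(xs2[int(np.argmax(np.abs(d2)))])


def make_record(ind, sex, value=None, *, side="right", burn_state="burnt", **kw):
    """One record with ``value`` as its maxh (other measurements via kwargs)."""
    fields = {"maxh": value}
    fields.update(kw)
    return MeasurementRecord(
        individual_id=str(ind), sex=sex, side=side, burn_state=burn_state, **fields
    )


@pytest.fixture
def toy_dataset():
    """Four burnt records: two female (30, 36), two male (40, 34) on maxh."""
    recs = [
        make_record("a", FEMALE, 30.0),
        make_record("b", FEMALE, 36.0),
        make_record("c", MALE, 40.0),
        make_record("d", MALE, 34.0),
    ]
    return StudyDataset(records=recs, provenance="toy")


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
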