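import math

import numpy as np
import pytest

from isobolo.probit import ProbitFit, estimable, fit_log_probit


def make_fit(
    agent_id: str,
    ed50: float,
    slope: float,
    sem: float = 1.0,
    n_effective: int = 24,
) -> ProbitFit:
    """Synthetic ProbitFit with an exact line through (log10 ed50, 5)."""
    a = 5.0 - slope * math.log10(ed50)
    return ProbitFit(
        agent_id=agent_id,
        intercept_a=a,
        slope_b=slope,
        ed50=ed50,
        log10_ed50=math.log10(ed50),
        sem_ed50=sem,
        ci95=(ed50 * 0.8, ed50 * 1.25),
        slope_function_S=10.0 ** (1.0 / slope),
        n_effective=n_effective,
        n_used_total=n_effective,
    )


def fit_or_none(dataset, doses):
    """Fit a dataset, returning None for degenerate/non-estimable replicates."""
    try:
        fit = fit_log_probit(dataset, ml_crosscheck=False)
    except ValueError:
        return None
    return fit if estimable(fit, doses) else None


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)
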