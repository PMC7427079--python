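import numpy as np
import pytest

import ctdikit as ck


@pytest.fixture(scope="session")
def ref():
    return ck.default_reference()


@pytest.fixture
def template():
    return ck.BeatTemplateParams()


def boundary_errors(truth, maps):
    """Absolute per-boundary errors (samples) between ground truth and maps."""
    errs = []
    for m in maps:
        b = min(truth.beats, key=lambda b: abs(b.start - m.start))
        for (gs, _), (ds, _) in zip(b.phase_bounds, m.phase_bounds):
            errs.append(abs(gs - ds))
        errs.append(abs(b.end - m.end))
    return np.array(errs)
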