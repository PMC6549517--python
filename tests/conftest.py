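import numpy as np
import pytest

import lvflow as lf
from lvflow.timing import TimingResult


@pytest.fixture(scope="session")
def duct():
    """Small duct phantom shared across test modules."""
    spec = lf.PhantomSpec(shape=(32, 32, 32))
    field, ed, es, gt = lf.make_duct_phantom(spec)
    return {"spec": spec, "field": field, "ed": ed, "es": es, "gt": gt}


@pytest.fixture(scope="session")
def duct_traced(duct):
    spec = duct["spec"]
    timing = TimingResult(ed_frame=spec.ed_frame, es_frame=spec.es_frame)
    seeds = lf.seed_grid(duct["ed"])
    pathlines = lf.trace_pathlines(duct["field"], seeds, timing)
    result = lf.analyze_lv_flow(
        pathlines, duct["es"], duct["ed"],
        late_onset_time=duct["gt"].meta["late_onset_time"],
    )
    return {**duct, "timing": timing, "seeds": seeds,
            "pathlines": pathlines, "result": result}


@pytest.fixture(scope="session")
def affine_rotation():
    spec = lf.PhantomSpec(phantom_kind="affine", shape=(32, 32, 32),
                          affine_motion="rotation", omega=np.pi)
    field, ed, es, gt = lf.make_affine_phantom(spec)
    return {"spec": spec, "field": field, "ed": ed, "es": es, "gt": gt}
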