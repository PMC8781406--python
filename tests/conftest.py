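import numpy as np
import pytest

from irifkit import synthetic as syn
from irifkit.irif import detect_foci
from irifkit.nucseg import segment_nuclei


@pytest.fixture(scope="session")
def detected_cell():
    """One rendered nucleus with 10 well-separated foci, run end to end.

    Session-scoped: several modules assert different invariants on the
    same detection result.
    """
    (nucleus, foci), = syn.generate_benchmark_population(
        n_cells=1, n_foci=10, min_separation_um=1.0, seed=11
    )
    stack, truth = syn.generate_nucleus_stack([nucleus], foci, seed=42)
    nuclei = segment_nuclei(stack)
    seeds, focus_labels, coloc = detect_foci(stack, nuclei)
    return {
        "nucleus_spec": nucleus,
        "focus_specs": foci,
        "stack": stack,
        "truth": truth,
        "nuclei": nuclei,
        "seeds": seeds,
        "foci": focus_labels,
        "coloc": coloc,
    }


@pytest.fixture
def small_geometry():
    return syn.StackGeometry(shape=(20, 64, 64), voxel_size=(0.3, 0.065, 0.065))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
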