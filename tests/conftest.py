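import numpy as np
import pandas as pd
import pytest

from epep import SampleDesign, default_registry


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def registry_full():
    """Registry without the non-*Triticum* exclusion."""
    return default_registry(exclude_non_triticum=False)


@pytest.fixture
def small_design():
    """2 species x 2 cultivars x 3 technical replicates."""
    samples = [
        ("wheat_cv1", "wheat", "cv1"),
        ("wheat_cv2", "wheat", "cv2"),
        ("einkorn_cv1", "einkorn", "cv1"),
        ("einkorn_cv2", "einkorn", "cv2"),
    ]
    reps = {s: [f"{s}_r{k}" for k in (1, 2, 3)] for s, _, _ in samples}
    return SampleDesign(samples=samples, replicates=reps)


def make_table(design, rows):
    """Build a MaxQuant-style peptide table from compact row specs:
    (sequence, proteins, score, reverse, contaminant, {run: intensity})."""
    recs = []
    for seq, prots, score, rev, con, intens in rows:
        rec = {
            "Sequence": seq,
            "Proteins": prots,
            "Score": score,
            "Reverse": "+" if rev else "",
            "Potential contaminant": "+" if con else "",
        }
        for run in design.run_ids:
            rec[f"Intensity {run}"] = intens.get(run, 0.0)
        recs.append(rec)
    cols = ["Sequence", "Proteins", "Score", "Reverse", "Potential contaminant"] + [
        f"Intensity {run}" for run in design.run_ids
    ]
    return pd.DataFrame(recs, columns=cols)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
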