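import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def match_steps(true_idx, found_idx, tol_frames=1):
    """Greedy one-to-one matching of detected to true step indices."""
    true_idx = np.sort(np.asarray(true_idx))
    found = sorted(np.asarray(found_idx).tolist())
    matched = 0
    for t in true_idx:
        for f in list(found):
            if abs(f - t) <= tol_frames:
                found.remove(f)
                matched += 1
                break
    return matched
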