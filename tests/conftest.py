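import numpy as np
import pytest

from cueconn import EpochSet, GcMatrix, VarSpec, simulate_var_epochs


@pytest.fixture
def white_noise_epochs():
    """3 epochs x 2 independent white-noise channels at 500 Hz."""
    spec = VarSpec([np.zeros((2, 2))])
    return simulate_var_epochs(spec, n_epochs=3, epoch_duration=4.0,
                               srate=500.0, seed=101)


@pytest.fixture
def var3_fixture():
    """Small 3-channel, 2-epoch VAR(2) fixture for oracle comparisons."""
    a1 = np.array([[0.4, 0.2, 0.0],
                   [0.3, 0.3, 0.0],
                   [0.0, 0.25, 0.35]])
    a2 = np.array([[-0.15, 0.0, 0.1],
                   [0.0, -0.1, 0.0],
                   [0.05, 0.0, -0.2]])
    spec = VarSpec([a1, a2])
    return simulate_var_epochs(spec, n_epochs=2, epoch_duration=0.8,
                               srate=500.0, seed=77)


def make_subject_matrix(pvals, F=None, labels=None, subject_id="S00",
                        condition="lexical"):
    """Build a subject-level GcMatrix from a square p-value array."""
    p = np.asarray(pvals, dtype=float)
    C = p.shape[0]
    diag = np.eye(C, dtype=bool)
    p = np.where(diag, np.nan, p)
    if F is None:
        F = np.where(diag, np.nan, 10.0)
    return GcMatrix(F=np.asarray(F, dtype=float), pvalue=p, df_num=2,
                    df_den=100.0, level="subject",
                    channel_labels=labels or [f"ch{i}" for i in range(C)],
                    subject_id=subject_id, condition=condition)
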