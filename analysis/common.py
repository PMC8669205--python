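"""Shared settings for the numbered analysis drivers.

Every driver regenerates the same synthetic cohort deterministically from
COHORT_SEED through the library, so the scripts can be run independently
and in any order; heavyweight NIfTI exports go under scratch/.
"""

from pathlib import Path

COHORT_SEED = 1
N_LESIONS = 15

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"


def cohort():
    """The default 15-lesion serial study and its ground truth."""
    from qmi.phantom import build_phantom, default_cohort_spec
    spec = default_cohort_spec(n_lesions=N_LESIONS, seed=COHORT_SEED)
    study, truth = build_phantom(spec)
    return spec, study, truth
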