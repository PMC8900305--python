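"""Shared study conditions for the analysis scripts.

Every script re-derives the same seeded cohort from this configuration, so
each one can be run standalone and all of them agree on the data.
"""

from pathlib import Path

from recessex.simdata import SimConfig

SEED = 1
CONFIG = SimConfig(seed=SEED)
_ROOT = Path(__file__).resolve().parent.parent
RESULTS = _ROOT / "results" / "analysis"
SCRATCH = _ROOT / "scratch" / "analysis_inputs"  # bulky simulated inputs


def outdir() -> Path:
    RESULTS.mkdir(parents=True, exist_ok=True)
    return RESULTS


def scratchdir() -> Path:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    return SCRATCH
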