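"""Shared setup for the numbered analysis drivers.

All drivers operate on the same deterministic seven-cohort synthetic
study (seed 20140221) so their outputs under results/ agree with one
another; each recomputes what it needs rather than reading another
driver's output.
"""

from __future__ import annotations

import sys
from pathlib import Path

from meqtl.pipeline import RunConfig, qc_cohort
from meqtl.scan import scan_cohort
from meqtl.simulate import SimConfig, simulate_study

RESULTS = Path(__file__).resolve().parent.parent / "results"
STUDY_SEED = 20140221


def study_config() -> SimConfig:
    return SimConfig(seed=STUDY_SEED)  # the default seven-cohort design


def run_config() -> RunConfig:
    return RunConfig(sim=study_config(), seed=STUDY_SEED)


def simulated_study():
    return simulate_study(study_config())


def clean_study():
    cohorts, truth = simulated_study()
    return [qc_cohort(ds) for ds in cohorts], truth


def scanned_study(scale: str = "beta"):
    clean, truth = clean_study()
    results = {ds.name: scan_cohort(ds, scale=scale) for ds in clean}
    return clean, truth, results


def announce(msg: str) -> None:
    print(msg, file=sys.stderr)
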