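"""Shared configuration for the numbered analysis drivers.

One cohort at the study scale (124 subjects, 111 nodes, 600 one-second
frames) with the urinary-lead-down / blood-zinc-up planted effect.  The
hyperparameter search budget is 25 random candidates (each scored by full
LOOCV); the search space itself matches the package default.
"""

from pathlib import Path

from neuroexposome.pipeline import RunConfig

WORKDIR = Path(__file__).resolve().parent.parent / "results" / "pipeline"


def study_config(seed: int = 1) -> RunConfig:
    return RunConfig(seed=seed, n_subjects=124, n_iter=25)
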