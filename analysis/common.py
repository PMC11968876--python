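"""Shared study configuration for the numbered analysis scripts.

One synthetic world, reused by every script: a 3-degree-wide coastal
domain with 80 Landsat-scale kelp pixels, 10 MPAs, a 5-model ensemble
under three SSP scenarios, daily SST 1983-2100, and the standard
heatwave/bias-correction settings.
"""

import logging

from kelpmhw.pipeline import RunConfig

RESULTS = "results/study"


def study_config(seed: int = 1) -> RunConfig:
    return RunConfig(seed=seed, out_dir=RESULTS, n_models=5,
                     n_kelp_pixels=80, n_mpas=10)


def setup_logging() -> None:
    logging.basicConfig(level=logging.WARNING)
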