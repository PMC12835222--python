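"""Analysis presets matched to the synthetic cohorts.

The field's customary expression filter ("CPM > 1 in enough samples") is
calibrated to real sequencing depths of tens of millions of reads, where
CPM 1 corresponds to tens of counts.  Simulated cohorts here carry a few
thousand genes and library sizes around 2e5, so the same CPM cutoff would
keep genes observed at a fraction of a count.  These presets transport
the filter to simulated depth (CPM 10 ~ 2 counts at the default library
size) and scale the empirical-control count to the simulated gene
universe (500 of ~2000 genes, mirroring the usual few-thousand-of-20k
proportion).
"""

from __future__ import annotations

from .de import DEConfig

__all__ = ["simulated_study_config"]


def simulated_study_config(**overrides) -> DEConfig:
    """DE configuration matched to ``CohortSpec`` default depth and size."""
    params = dict(cpm_filter=10.0, n_control_genes=500)
    params.update(overrides)
    return DEConfig(**params)
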