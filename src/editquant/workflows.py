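"""End-to-end workflows: build the standard models, simulate one sample, quantify.

Convenience layer used by scripts and tests; every step is the corresponding
library call, so results are identical to running the pipeline by hand.
"""

from __future__ import annotations

from dataclasses import dataclass

from .indel import IndelResult, run_indel_pipeline
from .lmu import AdapterSpec, ElementPanel, HdrResult, build_element_panel, run_lmu_pipeline
from .reference import (
    DonorModel,
    LocusModel,
    RestrictionEnzyme,
    VectorModel,
    build_donor_vector,
    build_nuclease_vector,
    build_synthetic_locus,
)
from .simulate import (
    AlleleMix,
    SimConfig,
    simulate_alleles,
    simulate_indel_reads,
    simulate_lmu_library,
    truth_table,
)

__all__ = ["StandardModels", "standard_models", "indel_sample", "hdr_sample"]


@dataclass(frozen=True)
class StandardModels:
    locus: LocusModel
    donor: DonorModel
    nuclease: VectorModel
    panel: ElementPanel


def standard_models(seed: int = 0) -> StandardModels:
    """Locus, donor, nuclease vector, and element panel at default geometry."""
    locus = build_synthetic_locus(seed=seed)
    donor = build_donor_vector(locus, seed=seed + 1)
    nuclease = build_nuclease_vector(seed=seed + 2)
    panel = build_element_panel(locus, donor, nuclease)
    return StandardModels(locus, donor, nuclease, panel)


def indel_sample(
    models: StandardModels,
    mix: AlleleMix,
    n_molecules: int,
    seed: int,
    *,
    sub_error_rate: float = 0.0,
    duplication: tuple = ("constant", 1),
) -> tuple[IndelResult, float]:
    """Simulate one amplicon-seq sample and quantify it.

    Returns the pipeline result and the realized truth-table indel fraction.
    """
    locus = models.locus
    alleles = simulate_alleles(
        locus, models.donor, mix, n_molecules, seed, nuclease=models.nuclease
    )
    cfg = SimConfig(
        n_molecules=n_molecules,
        duplication_dist=duplication,
        sub_error_rate=sub_error_rate,
        seed=seed + 1,
    )
    pairs = simulate_indel_reads(alleles, locus, cfg)
    amp_lo = locus.cleavage_pos - cfg.amplicon_halfwidth
    ref = locus.sequence[amp_lo : locus.cleavage_pos + cfg.amplicon_halfwidth + 1]
    result, _ = run_indel_pipeline(pairs, ref, locus.cleavage_pos - amp_lo)
    tt = truth_table(alleles)
    return result, float((tt.truth_label == "indel").mean())


def hdr_sample(
    models: StandardModels,
    mix: AlleleMix,
    n_molecules: int,
    seed: int,
    enzyme: RestrictionEnzyme,
    *,
    sub_error_rate: float = 0.0,
    duplication: tuple = ("geometric", 5),
    unique_umis: bool = False,
) -> tuple[HdrResult, float]:
    """Simulate one LMU-PCR sample and quantify it.

    Returns the pipeline result and the realized truth-table HDR fraction.
    """
    locus = models.locus
    alleles = simulate_alleles(
        locus, models.donor, mix, n_molecules, seed, nuclease=models.nuclease
    )
    cfg = SimConfig(
        n_molecules=n_molecules,
        duplication_dist=duplication,
        sub_error_rate=sub_error_rate,
        unique_umis=unique_umis,
        seed=seed + 1,
    )
    pairs, truth = simulate_lmu_library(alleles, enzyme, locus, cfg)
    result, _ = run_lmu_pipeline(
        pairs,
        locus,
        models.panel,
        enzyme,
        adapter_spec=AdapterSpec(cfg.adapter, cfg.umi_length),
    )
    return result, float((truth.truth_label == "HDR").mean())
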