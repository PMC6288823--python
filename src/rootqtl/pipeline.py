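"""End-to-end driver: simulate a study, call trait QTL, run DE, fine-map,
and test candidate genes against the planted truth."""

from __future__ import annotations

from dataclasses import dataclass

from . import bin_mapping, eqtl_de, synthetic_data, trait_qtl


@dataclass
class EndToEndResult:
    scenario: synthetic_data.Scenario
    trait_fit: trait_qtl.TraitModelFit
    bins: list
    bin_calls: list
    candidates: list
    causal_bin_candidate: bool
    causal_gene_recovered: bool


def run_end_to_end(seed: int, n_seedlings: int = 35, n_reps: int = 3,
                   trait_alpha: float = 0.01, de_alpha: float = 0.01,
                   min_ils: int = 2, min_mean: float = 5.0,
                   scenario: synthetic_data.Scenario | None = None
                   ) -> EndToEndResult:
    """Run the full inference chain on the default synthetic scenario.

    Steps: simulate seedling traits and expression counts; call angle QTL
    with the mixed model (q ≤ ``trait_alpha``); build bins and fine-map by
    significant/non-significant IL exclusion; run exact-test DE for every
    trait-significant IL against the reference (the only DE tables the
    consistency test consumes); and apply the trait-consistency test.
    Recovery holds when the planted causal gene sits in a candidate bin and
    survives the consistency test.
    """
    if scenario is None:
        scenario = synthetic_data.default_scenario(seed)
    genome, panel, truth = scenario.genome, scenario.panel, scenario.truth
    ref = scenario.reference_id

    records = synthetic_data.simulate_trait(panel, genome, truth,
                                            n_seedlings=n_seedlings, seed=seed + 1)
    trait_fit = trait_qtl.fit_trait_model(records, ref, alpha=trait_alpha)
    sig = trait_fit.significant_ils()
    nonsig = set(trait_fit.effects.index) - sig

    bins = bin_mapping.compute_bins(panel, genome.genes)
    bin_calls = bin_mapping.fine_map(bins, sig, nonsig)

    matrix = synthetic_data.simulate_expression(
        panel, genome, truth, n_reps=n_reps, seed=seed + 2, reference_id=ref,
        base_mean_overrides=scenario.base_mean_overrides)
    panel_by_id = {il.il_id: il for il in panel}
    de_by_il = {}
    for il_id in sorted(sig):
        de = eqtl_de.call_de(matrix, il_id, ref, alpha=de_alpha)
        de_by_il[il_id] = eqtl_de.classify_cis_trans(de, panel_by_id[il_id],
                                                     matrix.genes)
    candidates = bin_mapping.consistency_test(de_by_il, trait_fit.effects, bins,
                                              bin_calls=bin_calls, min_ils=min_ils,
                                              min_mean=min_mean, alpha=de_alpha)
    candidates = bin_mapping.attach_rankings(candidates, de_by_il,
                                             trait_fit.effects, ref)

    causal = scenario.causal_gene
    causal_bin = bin_mapping.bin_of_gene(bins, causal)
    calls_by_bin = {c.bin_id: c for c in bin_calls}
    causal_bin_candidate = (causal_bin is not None
                            and calls_by_bin[causal_bin.bin_id].status == "candidate")
    recovered = causal_bin_candidate and any(c.gene_id == causal for c in candidates)
    return EndToEndResult(scenario, trait_fit, bins, bin_calls, candidates,
                          causal_bin_candidate, recovered)
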