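"""Ready-made simulation configurations with planted signals."""

from __future__ import annotations

from .simulate import PedigreeSpec, SimulationConfig, VariantSpec

__all__ = ["default_simulation_config"]


def default_simulation_config(seed: int = 0, n_families: int = 30,
                              n_sporadic_cases: int = 40,
                              n_controls: int = 30) -> SimulationConfig:
    """A corpus with a linkage-style common risk variant shared across
    families, a zero-population-AF variant planted in two large families,
    and a background of neutral variants spanning the AF spectrum."""
    variants = [
        # linkage-strategy target: rare, damaging, planted into several families;
        # infinite family penetrance makes planted carriers deterministically CD
        VariantSpec("16", 50_763_778, "G", "GC", gene="GENE_L", founder_af=0.02,
                    consequence="frameshift", carol=None, cadd=None,
                    effect="L1007insC", af_aj=0.03, af_nfe=0.02, af_paj=0.025,
                    odds_ratio=3.0, family_or=float("inf"),
                    target_families=("F3", "F4", "F5"), min_planted_carriers=2),
        # rare-strategy target: absent from the population, two lfams share it
        VariantSpec("5", 71_000_000, "C", "T", gene="GENE_R", founder_af=0.0,
                    consequence="missense", carol="damaging", cadd=28.0,
                    effect="S332R", af_aj=None, af_nfe=None, af_paj=None,
                    af_aj_wgs=0.0, odds_ratio=8.0, family_or=float("inf"),
                    target_families=("F1", "F2"), min_planted_carriers=4),
    ]
    # neutral background spanning the founder AF spectrum
    for i, af in enumerate((0.001, 0.004, 0.01, 0.02, 0.04, 0.05, 0.2, 0.4)):
        variants.append(VariantSpec(
            chrom=str(1 + i % 4), pos=10_000_000 + i * 1_000_000,
            ref="A", alt="G", gene=f"GENE_N{i}", founder_af=af,
            consequence="missense", carol="damaging" if i % 2 else "benign",
            cadd=25.0 if i % 2 else 10.0,
            af_aj=af, af_nfe=max(af * 0.8, 1e-5), af_paj=None,
        ))
    return SimulationConfig(
        seed=seed, n_families=n_families, n_lfams=4,
        n_sporadic_cases=n_sporadic_cases, n_controls=n_controls,
        pedigree=PedigreeSpec(n_generations=3, sibship_size=3, seq_prob=0.95),
        baseline_prevalence=0.05, familial_sd=2.0,
        variants=variants,
    )
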