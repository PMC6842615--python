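"""Rosette self-assembly on micropatterned fields at two adhesion levels.

Runs the agent-based model (random motility + proximity-triggered apical
attachment) on 140-um fields for 48 h, comparing control-like attachment
efficiency with a strongly reduced, mutant-like one.
"""

from corticlone.rosette import (
    AdhesionParams,
    FieldSpec,
    MotilityParams,
    compare_center_distributions,
    simulate_chip,
)

spec, motility = FieldSpec(), MotilityParams()
chips = {}
for label, p_attach in [("control-like", 0.1), ("mutant-like", 0.008)]:
    chip = simulate_chip(150, spec, motility, AdhesionParams(p_attach=p_attach),
                         t_end=48.0, seed=5)
    chips[label] = chip
    print(f"{label:13s} (p_attach={p_attach}): "
          f"single-rosette fields {chip.single_rosette_fraction:.2f}, "
          f"mean rosettes/field {chip.mean_rosettes_per_field:.2f}")

d, p = compare_center_distributions(chips["control-like"].center_distances,
                                    chips["mutant-like"].center_distances)
print(f"\nrosette-center distance distributions: KS D = {d:.3f}, p = {p:.3g}")
print("Reduced apical attachment lowers the fraction of fields organized "
      "into a single rosette — the impaired self-assembly phenotype.")
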