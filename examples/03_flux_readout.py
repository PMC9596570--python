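"""The autophagic-flux readout: dual GFP+mRFP puncta counts per cell.

GFP fluorescence is quenched in acidic compartments while mRFP persists, so
puncta positive in both channels mark neutral-pH autophagosomes; their
accumulation under bafilomycin A1 (which blocks lysosomal acidification)
measures flux.  Here two simulated cells differ threefold in their true
dual-puncta load, and the fixed-cell pipeline recovers the contrast.
"""

import mitoflux as mf
from mitoflux.pipeline import PipelineConfig, analyze_scene

config = PipelineConfig(mode="fixed_cell")
for label, n_dual, seed in [("control", 4, 10), ("BafA1", 12, 11)]:
    spec = mf.SceneSpec(seed=seed, n_dual=n_dual, n_gfp_only=3, n_rfp_only=3,
                        frac_near_mito=0.5)
    truth, scene = mf.simulate_scene(spec)
    res = analyze_scene(scene, config, roi=truth.cell_mask, cell_id=label,
                        condition=label)
    s = res.summary
    print(f"{label:8s}: {s.n_gfp} GFP, {s.n_rfp} mRFP, {s.n_dual} dual "
          f"({s.n_dual_near_mito} within 5 px of mitochondria, "
          f"fraction {s.fraction_near_mito:.2f})")
# The dual count tracks the simulated flux level; the near-mitochondria
# fraction measures association of autophagosomes with the mitochondrial
# network (the mitophagy readout).
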