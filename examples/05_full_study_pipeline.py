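"""End-to-end synthetic study: simulate, measure, and contrast regions.

Generates a small clustered study (2 animals × 1 cell for control and
border), runs the complete pipeline (components → records → per-cell
summaries → mixed-model contrasts) and prints the regional comparisons.
The border arm is constructed with dilation, dropout and fragments, so
the signs of the contrasts are known in advance.
"""

import tempfile
from pathlib import Path

import ttmorph as tm
from ttmorph.pipeline import run_pipeline, simulate_study

workdir = Path(tempfile.mkdtemp(prefix="ttmorph_study_"))
config = simulate_study(
    control=tm.control_spec(cell_width=5.0, cell_depth=0.9, n_zlines=2),
    remote=None,
    border=tm.border_spec(cell_width=5.0, cell_depth=0.9, n_zlines=2,
                          fragment_count=2),
    n_animals=2, n_cells=1, seed=5, outdir=workdir)

result = run_pipeline(config)
print(f"{len(result['components'])} components across {len(result['cells'])} cells")
print(f"report bundle: {result['output_dir']}\n")
for c in result["comparisons"]:
    print(f"{c.metric:32s} {c.regions[0]} vs {c.regions[1]}: "
          f"estimate {c.estimate:+9.4f} (transform {c.transform:8s}) "
          f"p = {c.p_value:.3f}")
print("\npositive diameter and fragment-density estimates, negative tubule-density")
print("estimate: the constructed border-zone remodelling, recovered end to end.")
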