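"""Generate a synthetic islet-style single-cell dataset and write it to disk.

The dataset has two conditions (ND and T2D), one planted co-expression
module active only in T2D (the dark genes), and matched per-gene
marginals, so only the association structure differs between conditions.
"""

from pathlib import Path

import ccsn
from ccsn import io as cio

spec = ccsn.default_dark_spec(seed=1)
expr, ann = ccsn.generate_expression(spec)

out = Path("scratch_example_data")
out.mkdir(exist_ok=True)
cio.write_expression(expr, out / "expression.tsv")
cio.write_annotation(ann, out / "annotation.tsv")

zero_frac = (expr.values == 0).mean()
print(f"matrix: {expr.n_genes} genes x {expr.n_cells} cells, "
      f"zero fraction {zero_frac:.2f}")
print(f"groups: {sorted(set(zip(ann.table.cell_type, ann.table.condition)))}")
print(f"planted dark genes: {[f'G{i:04d}' for i in spec.dark_genes]}")
print(f"written to {out}/")
# The dark genes share a latent factor (rho = 0.8) only in T2D cells;
# their per-gene means and variances are identical in both conditions.
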