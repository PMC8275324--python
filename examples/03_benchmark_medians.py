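"""A miniature benchmark: medians over a small simulation grid.

Runs the full simulate -> estimate -> call -> score pipeline over a
reduced grid (two locus-panel sizes x two ADO rates x two seeds) and
prints median precision/recall/F1 per cell and pooled.  The full-size
study grid lives in ``scripts/acceptance.py``.
"""

from scdoublet import aggregate_medians, copy_neutral_grid, run_grid

configs = copy_neutral_grid(ms=(50, 100), betas=(0.0, 0.25), seeds=(1, 2))
reports = run_grid(configs)

per_cell = aggregate_medians(reports, ["m", "beta"])
cols = ["m", "beta", "precision", "recall", "f1"]
print(per_cell[cols].to_string(index=False, float_format="%.3f"))

pooled = aggregate_medians(reports)
print("\npooled medians: precision=%.3f recall=%.3f f1=%.3f"
      % (pooled["precision"].iloc[0], pooled["recall"].iloc[0],
         pooled["f1"].iloc[0]))
# more loci and more dropout both help: extra loci add evidence per droplet,
# and dropout creates the 1/3 / 2/3 VAF signature that exposes doublets
# sharing identical or nested genotypes
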