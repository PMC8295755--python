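"""Run the whole pipeline (simulate -> SPI -> events -> response ->
stability -> repeatability -> evolvability -> report) into ./pipeline_out.

Equivalent to `droughtgen all --config cfg.yaml` from the shell.
"""

from pathlib import Path

import pandas as pd

from droughtgen.config import RunConfig
from droughtgen.pipeline import run_all

out = Path("pipeline_out")
cfg = RunConfig(seed=42, out_dir=str(out), sim_provenances=6, sim_trees=10,
                spi_scales=[1, 3, 6, 12])
run_all(cfg)

print("artifacts written to", out)
for p in sorted(out.iterdir()):
    print("  ", p.name)

an = pd.read_csv(out / "anova_species.csv")
print("\nspecies-level two-way ANOVA (both simulated trials):")
print(an[["trait", "term", "df", "F", "p"]].round(4).to_string(index=False))

rep = pd.read_csv(out / "repeatability_species.csv")
print("\nspecies repeatability summary:")
print(rep[["site_id", "trait", "r_sp", "se_sp", "n_sig", "n_prov"]].round(3).to_string(index=False))
print("\nRerunning with the same config reproduces every file byte for byte.")
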