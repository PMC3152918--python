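"""File-based pipeline run: simulate -> filter -> count -> contrast -> report.

The same stages as the library calls, but through the staged runner that
reads and writes the TSV/FASTA/BED dialects and records a manifest — the
workflow used for real SNP tables, exercised here on synthetic inputs.
Equivalent shell usage:  mutcontext run-all --config run.yaml
"""

import json
import tempfile
from pathlib import Path

import pandas as pd

from mutcontext import SimulationConfig
from mutcontext.pipeline import RunConfig, run_all

with tempfile.TemporaryDirectory() as tmp:
    config = RunConfig(
        outdir=tmp,
        seed=8,
        simulation=SimulationConfig(
            genome_length=2_000_000, planted_effects={"C>T|1,CG": 5.0}, seed=8
        ),
    )
    paths = run_all(config)
    print("outputs:", sorted(p.name for p in Path(tmp).iterdir()))

    manifest = json.loads((Path(tmp) / "manifest.json").read_text())
    filt = manifest["stages"]["filter"]
    print(
        f"filter stage: {filt['input']} SNPs in, {filt['accepted']} accepted, "
        f"rejections {filt['rejections']}"
    )
    # input = accepted + sum(rejections): the manifest's conservation line.

    table = pd.read_csv(paths["contrast_table"], sep="\t")
    top = table.nlargest(2, "minimal_contrast")
    print(top[["context", "mutation_bias", "minimal_contrast"]].to_string(index=False))
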