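"""Full pipeline on files: simulate, filter, estimate, summarize.

Writes a synthetic exome-depth patient to a temporary directory, runs
the complete pipeline from the files on disk (candidates VCF +
observation TSV + YAML run config), and prints the summary.
"""

import json
import tempfile
from pathlib import Path

from click.testing import CliRunner

from tinc.cli import main

workdir = Path(tempfile.mkdtemp(prefix="tinc_demo_"))
runner = CliRunner()

res = runner.invoke(
    main, ["simulate", "--preset", "patient1-wes", "--out", str(workdir), "--seed", "1"]
)
assert res.exit_code == 0, res.output

res = runner.invoke(main, ["run", "--config", str(workdir / "run_config.yaml")])
assert res.exit_code == 0, res.output

summary = json.loads((workdir / "results" / "summary.json").read_text())
att = summary["attrition"]
print(f"candidates: {att['candidates']}, survivors: {att['survivors']}")
for sample_id, block in sorted(summary["samples"].items()):
    print(
        f"{sample_id:<24} condition={block['condition']:<12} "
        f"present {block['n_with_mutant_read']}/{block['n_snvs']}  "
        f"median c = {100 * block['median_contamination']:.2f}%"
    )
print(f"(outputs under {workdir}/results: verdicts.tsv, estimates.tsv, summary.json)")
# Exome depth (~200X) separates heavy from light contamination; the
# ultra-deep targeted presets (see 04) give the precise estimates.
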