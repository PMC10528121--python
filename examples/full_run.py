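"""One reproducible end-to-end run: simulate a session, compare the models,
run the ERP stage, and write every artifact to a run directory."""

import json

from trustwalk import RunConfig, run_all

config = RunConfig(seed=42, output_dir="runs/example")
outdir = run_all(config)

print("artifacts in", outdir)
for path in sorted(outdir.iterdir()):
    print("  ", path.name)

comparison = json.loads((outdir / "comparison.json").read_text())
print(f"\nRMSE markov={comparison['rmse_markov']:.3f} "
      f"quantum={comparison['rmse_quantum']:.3f}")
summary = json.loads((outdir / "erp_summary.json").read_text())
print("mismatch central peak:",
      round(summary["peaks_central_300_500"]["mismatch"]["amplitude_uv"], 2), "uV at",
      summary["peaks_central_300_500"]["mismatch"]["latency_ms"], "ms")
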