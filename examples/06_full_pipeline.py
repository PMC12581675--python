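"""One-call orchestration: simulate -> preprocess -> ratios -> embed -> stats.

Equivalent to the CLI `ramanfp run --demo --seed 0 --out out/`. All outputs
are plain CSV/JSON plus a manifest with content hashes; a rerun with the
same seed reproduces every data file byte for byte.
"""

from pathlib import Path

from ramanfp import demo_config, run_pipeline

out = Path("scratch/demo_run")
manifest = run_pipeline(demo_config(out, seed=0))

print("stages:")
for stage, rec in manifest["stages"].items():
    print(f"  {stage}: {rec}")
print("\noutput files:")
for name in sorted(manifest["files"]):
    print(f"  {out / name}")
print(f"\nconfig hash {manifest['config_hash']}, elapsed {manifest['elapsed_s']}s")
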