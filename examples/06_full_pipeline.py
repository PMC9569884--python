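"""Run the whole pipeline (simulate -> screen -> select -> evaluate -> score)
with one config and inspect the manifest it writes.

Every stage's outputs land as TSV tables under one directory; the JSON
manifest records the seed, thresholds and file list, and rerunning with
the same seed reproduces every table byte for byte.
"""

from necsig import RunConfig, run_all

config = RunConfig(out_dir="scratch/pipeline_demo", seed=1)
manifest = run_all(config)

print("stages:", " -> ".join(s["name"] for s in manifest["stages"]))
for stage in manifest["stages"]:
    info = {k: v for k, v in stage.items() if k != "name"}
    print(f"  {stage['name']}: {info}")
print("output tables:")
for key, path in manifest["files"].items():
    print(f"  {key}: {path}")
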