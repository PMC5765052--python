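"""Config-driven end-to-end run: phantoms -> measurements -> statistics.

Builds a small two-group study of vertebral-column phantoms where the Ach
animals are more kyphotic, measures every animal, and reports the group
comparison — the same flow a YAML config drives from the command line
(`skelemorph run config.yaml`).
"""

from skelemorph import pipeline

samples = []
i = 0
for genotype in ("WT", "Ach"):
    for k in range(5):
        i += 1
        samples.append({
            "animal_id": f"A{i:02d}",
            "genotype": genotype,
            "sex": "M" if k % 2 else "F",
            "age_weeks": 3,
            "phantom": {
                "kind": "vertebral_column",
                "params": {"chord": 20.0,
                           "sagitta": 3.5 + 0.2 * k if genotype == "WT" else 6.0 + 0.4 * k},
                "spacing": 0.2,
                "seed": i,
            },
            "measurements": ["kyphosis_index"],
        })

result = pipeline.run_pipeline({"samples": samples})
print(result.table.df.to_string(index=False))
for c in result.comparisons:
    print(f"\n{c.measurement_name}: WT {c.mean_wt:.2f}±{c.sem_wt:.2f} vs "
          f"Ach {c.mean_ach:.2f}±{c.sem_ach:.2f}, p={c.p_value:.3g} {c.stars}")
print("Lower kyphosis index = more kyphotic; the Ach group's larger spinal")
print("sagitta produces the expected significant reduction.")
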