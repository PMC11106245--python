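"""Generate a synthetic three-cohort serum study and derive endpoint labels.

The generator emulates a CLIMB-like cohort (lesion counts + annualized
relapse rate), an EPIC-like cohort (lesion counts), and an ACP-like cohort
(relapse status), with assay batches, bridge aliquots, demographic effects
and sparse true protein-endpoint effects anchored on an NfL analog.
"""

from mspanel import (
    GeneratorConfig,
    bin_lesion_counts,
    derive_binary_labels,
    filter_gd_window,
    generate_cohorts,
)

config = GeneratorConfig(
    n_proteins=30,
    rng_seed=1,
    n_samples={"CLIMB-like": 150, "EPIC-like": 80, "ACP-like": 60},
)
expression, manifest, truth = generate_cohorts(config)
print(f"expression matrix: {expression.shape[0]} samples x {expression.shape[1]} proteins")
print(f"bridge rows: {int(manifest['is_bridge'].sum())} "
      f"({config.n_bridge} aliquots x {config.n_batches} batches)")

# Lesion endpoints only trust samples drawn within 30 days of the MRI.
filtered = filter_gd_window(manifest)
n0, n1, n2, n3 = bin_lesion_counts(filtered)
print(f"lesion bins (0 / 1 / 2 / >=3): {n0} / {n1} / {n2} / {n3}")

for endpoint in ("GDA", "SDA", "EDA", "CRS", "ARR"):
    counts = derive_binary_labels(filtered, endpoint).counts()
    print(
        f"{endpoint}: {counts['positive']} positive, {counts['negative']} negative, "
        f"{counts['excluded']} excluded"
    )
# GDA contrasts 0 lesions vs any; SDA vs exactly 1; EDA vs >=3; CRS is
# relapse vs remission; ARR is binarized at <=0.2 (low) / >=1.0 (high).
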