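"""Run a small benchmark experiment and print the MR/BR summary table.

For each knowledge case, ten replicates pair a fresh dataset with a fresh
simulated knowledge set; MR rows are means over replicates and BR rows the
best single replicate.  Expect mean SHD to drop from the data-only baseline
as knowledge is added.
"""

import hybridbn as hb

N, V = 1000, 0.6
for case in ("none", "explicit", "ev"):
    config = hb.ExperimentConfig(network="asia", sample_sizes=(N,),
                                 n_datasets=5, case=case, v_values=(V,),
                                 placement="both", seed=0)
    result = hb.run_experiment(config)
    summary = result.summary(N, 0.0 if case == "none" else V)
    label = "data" if case == "none" else case
    row = summary.rounded()
    print(f"{label:9s} MR: SHD={row['MR_SHD']} A={row['MR_A']} D={row['MR_D']} "
          f"I={row['MR_I']} C={row['MR_C']} | BR: SHD={row['BR_SHD']}")
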