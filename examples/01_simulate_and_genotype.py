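"""Simulate one subject's two multiplex PCR runs and genotype them.

Draws a genotype from the panel's allele frequencies, renders full
four-channel electropherograms (amplicons + stutter + ROX ladder + noise)
for both multiplex groups, and runs the complete detect -> ladder-match ->
Local Southern -> call pipeline.
"""

import numpy as np

import msatpipe as mp

panel = mp.builtin_panel()
rng = np.random.default_rng(42)

genotype = mp.sample_genotype(panel, rng=rng, subject="demo")
traces = {g: mp.simulate_run(genotype, panel, g, rng=rng)[0] for g in (1, 2)}
profile = mp.genotype_sample(traces, panel, run_id="demo")

expected = genotype.expected_bins()  # template sizes + 1 nt adenylation
print(f"{'marker':<10}{'called bins':<16}{'expected':<14}flags")
for marker in panel.marker_names:
    called = [c.bin for c in profile.calls[marker]]
    flags = ",".join(profile.flags.get(marker, [])) or "-"
    print(f"{marker:<10}{str(called):<16}{str(list(expected[marker])):<14}{flags}")

# Called bins are apparent sizes (template + 1 nt from full adenylation);
# a single call means the marker is homozygous.
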