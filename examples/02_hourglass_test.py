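"""Early-vs-middle permutation test on a simulated hourglass transcriptome.

Simulates 2000 genes across 11 stages where middle-peaking genes carry
lower ω₀ (stronger purifying selection) and higher protein connectivity,
then asks whether the weighted index is significantly lower (resp. higher)
in the middle period than early.  Small p-values support the hourglass
model; non-significance supports early conservation.
"""
import devotei as d

cfg = d.SimulationConfig(pattern="hourglass", seed=42)
expr, timeline, annotation, _ = d.generate_dataset(cfg)
weights = d.transform_expression(d.normalize_cpm(expr), "log2")

for parameter, direction in [("omega0", "middle_lower"), ("connectivity", "middle_higher")]:
    res = d.permutation_test(
        weights, annotation[parameter], timeline,
        direction=direction, n_perm=10_000, seed=1,
    )
    print(
        f"{parameter:>12}: Δe–m = {res.delta_observed:+.4f}  "
        f"p_normal = {res.p_normal:.2e}  p_empirical = {res.p_empirical:.2e}  "
        f"({direction})"
    )
print(
    "\nBoth parameters reject the no-coupling null: middle development is"
    "\nenriched for low-ω₀, high-connectivity genes, as simulated."
)
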