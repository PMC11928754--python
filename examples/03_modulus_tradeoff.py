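"""Effect of the prefix-free-parsing modulus on the backbone.

The modulus p sets the expected phrase length (about p symbols): a smaller
modulus yields shorter phrases, hence a finer parse in which more
multiMUM anchors survive divergence -- at the cost of a larger parse.
On the same input, the backbone at p = 20 should contain at least as many
anchors, covering at least as many bases before extension, as at p = 100.
"""

from panmum import FixtureParams, PfpParams, build_backbone, generate

_, seqs, _ = generate(FixtureParams(ancestor_length=30_000, m=5, snp_rate=1e-3, seed=17))
texts = [s.residues for s in seqs]
total = sum(len(t) for t in texts)

for modulus in (100, 20):
    anchors, stats = build_backbone(texts, pfp_params=PfpParams(window=10, modulus=modulus))
    cov_chain = 100.0 * stats.covered_bases_chain / total
    cov_ext = 100.0 * stats.covered_bases_extended / total
    print(
        f"modulus {modulus:>3}: {stats.phrase_count:5d} phrases, "
        f"{stats.multimum_count:4d} multiMUMs, {stats.anchor_count:4d} anchors | "
        f"coverage {cov_chain:5.2f}% after chaining, {cov_ext:5.2f}% after extension"
    )
print("\nthe finer parse (modulus 20) anchors more sequence before extension;")
print("extension then narrows the difference on SNP-only divergence")
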