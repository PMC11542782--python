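"""Project the learned 32-d embedding to 2-D with PCA and plot it.

Compact, well-separated clusters are what make a simple k-NN suggester
sufficient as the final classifier; overlap in the plot may be a projection
artifact rather than real confusion in 32-D.
"""

from pathlib import Path

from crfmap import RunConfig, SynthConfig, generate_corpus, plot_embedding, run_train

out = Path("scratch")
out.mkdir(exist_ok=True)

gt = generate_corpus(SynthConfig(n_classes=6, support=50, seed=31))
fitted = run_train(gt.corpus, RunConfig(seed=31))
plot_embedding(fitted.encoder, gt.corpus, out / "embedding_pca.png")
print(f"wrote {out / 'embedding_pca.png'}: one point per field, colored by "
      "SDTM target; tight single-color clusters = learnable classes")
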