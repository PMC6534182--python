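"""End-to-end: train the relation classifier on a synthetic corpus.

Generates an easy corpus (every positive sentence carries its class's
trigger keyword), trains with the standard protocol (cross-entropy,
RMSProp lr 0.001, batch 64, dropout 0.5, early stopping on validation
micro-F) and prints the evaluation report plus the attention keywords
the model learned to focus on.
"""

from chemrel.pipeline import ExperimentConfig, run_experiment
from chemrel.synthetic import SynthConfig, generate_corpus
from chemrel.train import TrainConfig

corpus = generate_corpus(SynthConfig(n_docs=300, sentences_per_doc=(4, 7),
                                     seed=7))
result = run_experiment(
    corpus.documents, corpus.mentions, corpus.relations,
    ExperimentConfig(bilm_epochs=3),
    TrainConfig(max_epochs=30, patience=30),
    seed=3,
    log=print,
)
print(f"\nbest validation micro-F {result.run.best_val_micro_f:.3f} "
      f"at epoch {result.run.best_epoch}")
print("\nvalidation-split report:")
print(result.report.render())
# The keyword lists show which tokens receive the most attention-pooling
# weight per predicted class; on this corpus they should recover the
# planted triggers (inhibitor/agonist/antagonist/...).
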