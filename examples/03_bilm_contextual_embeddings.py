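"""Train the small bidirectional language model and inspect its output.

The bi-LM maximizes the joint forward + backward log-likelihood; its
embedding layer and LSTM layers form a representation stack mixed with
softmax-normalized weights, so the same token receives different
vectors in different sentences.
"""

import numpy as np

from chemrel.bilm import BiLMConfig, embed_sentence, train_bilm

rng = np.random.default_rng(0)
# toy corpus: token 3 is followed by 4, token 5 by 6
sequences = [np.array([2, 3, 4, 7]), np.array([2, 5, 6, 7])] * 50

model, history = train_bilm(sequences, BiLMConfig(vocab_size=8, hidden_dim=8),
                            seed=0, epochs=10, lr=1e-2)
print("per-token negative log-likelihood by epoch:",
      [round(h, 3) for h in history])
print(f"perplexity: {model.perplexity(sequences[:2]):.2f} "
      f"(uniform would be {8:.1f})")

lp_f = model.log_likelihood([2, 3, 4, 7], "forward")
lp_b = model.log_likelihood([2, 3, 4, 7], "backward")
print("forward  log p per token:", np.round(lp_f, 3))
print("backward log p per token:", np.round(lp_b, 3))
print("joint objective:", round(model.joint_log_likelihood([2, 3, 4, 7]), 3),
      "= forward sum + backward sum")

a = embed_sentence([2, 3, 4, 7], model).matrix
b = embed_sentence([7, 4, 3, 2], model).matrix
print("\nsame token, different contexts, vector distance:",
      round(float(np.linalg.norm(a[1] - b[2])), 3),
      "(a static embedding would give 0.0)")
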