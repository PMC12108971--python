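"""Pre-train the categorical embedding layer and strip its output node.

A one-hidden-layer network is trained on the fracture label from the ten
ordinal codes; removing its output node leaves a map from 10 codes to a
20-dimensional dense vector.  The script verifies the stripping identity
and prints one embedded record.
"""

import numpy as np

from tsfnn import EmbeddingConfig, build_codebook, embed, encode_dataset, generate, pretrain_embedding, study_spec
from tsfnn.embedding import represent_codes

dataset = generate(study_spec(seed=1))
codebook = build_codebook(dataset.schema)
codes = encode_dataset(dataset, codebook)
labels = np.array(dataset.labels)

config = EmbeddingConfig(hidden_width=20, epochs=100, seed=0)
layer, net = pretrain_embedding(codes, labels, config, return_network=True)

vec = embed(codes[0], layer)
print(f"record 0 codes  : {codes[0].tolist()}")
print(f"embedded vector : length {len(vec)}, first 5 = {np.round(vec[:5], 3).tolist()}")

x = represent_codes(codes, layer.input_representation, layer.max_code)
hidden = net.layers[1].forward(net.layers[0].forward(x, False), False)
print(f"stripping exact : {np.array_equal(layer.transform(codes), hidden)}")
print("(the embedding equals the pre-training network's hidden activations)")
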