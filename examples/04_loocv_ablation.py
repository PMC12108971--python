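"""Leave-one-out comparison of architectures, mirroring the ablation tables.

Runs LOOCV for the fusion network with and without batch normalization on
the frozen 97/48 study-composition fixture and prints the two-row table
plus the improvement row.  Expect a few minutes of runtime.
"""

from tsfnn import ModelSpec, compare, load_study_fixture

dataset = load_study_fixture()
print(f"dataset: {len(dataset)} teeth, {sum(dataset.labels)} fractured\n")


def spec(**kw):
    s = ModelSpec(architecture="tsfnn", epochs=100, seed=0, **kw)
    s.embedding.epochs = 100
    return s


table = compare(
    dataset,
    [spec(use_batch_norm=False), spec(use_batch_norm=True)],
    names=["tsfnn", "tsfnn + batch norm"],
    master_seed=0,
)
print(table.round(3).to_string(index=False))
print("\n(each row pools 145 single-prediction folds into one confusion")
print(" matrix; the improvement row is the difference of the two rows)")
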