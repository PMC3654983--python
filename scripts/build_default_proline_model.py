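"""Regenerate the shipped proline spacing model.

The packaged model (src/prionscan/data/proline_model_default.tsv) is trained
on 5,000 synthetic background-composition sequences — a synthetic,
fully-reproducible stand-in for a non-redundant protein reference database.
Rerun this script only when the generator or background composition changes.
"""

from pathlib import Path

from prionscan.fixtures import GeneratorSpec, sample_sequences
from prionscan.proline import train_proline_model

SEED = 20130510
N_SEQUENCES = 5_000

def main() -> None:
    spec = GeneratorSpec.background(min_length=100, max_length=600)
    records = sample_sequences(spec, N_SEQUENCES, seed=SEED, id_prefix="REF")
    model = train_proline_model(records, max_distance=60)
    dest = Path(__file__).resolve().parents[1] / "src/prionscan/data/proline_model_default.tsv"
    model.save(dest)
    print(f"wrote {dest} (n_pairs={model.n_pairs})")

if __name__ == "__main__":
    main()
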