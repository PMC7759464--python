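#!/usr/bin/env python
"""Simulate the labelled training data and train the window classifier.

Generates balanced neutral/shared/divergent loci under the desk profile
(strong-selection regime), trains the convolutional classifier ensemble and
reports held-out test performance.  Writes the serialized model to
results/classifier.npz and the report to results/classifier_report.json.
(The genome-scan driver, 04_scan_genome.py, trains its own ensemble with the
scanned cohort's accessibility mask mirrored into the simulations.)

The per-class counts default to the desk scale (400 train / 200 test); the
full-scale run of the study design (4,000 / 2,000 per class, 1.05-Mb loci)
is reached with --paper-scale and correspondingly more patience.
"""

import argparse
import json
import pathlib

import numpy as np

from sweepscan import simulate as sim
from sweepscan.classifier import instances_to_features, train_classifier


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-train", type=int, default=400)
    ap.add_argument("--n-test", type=int, default=200)
    ap.add_argument("--s", type=float, default=0.1, help="selection coefficient (None draws it)")
    ap.add_argument("--paper-scale", action="store_true")
    ap.add_argument("--out-dir", default="results")
    args = ap.parse_args()

    rng = np.random.default_rng(args.seed)
    if args.paper_scale:
        prof = sim.ScaleProfile()
        model = sim.desk_model()  # supply fitted parameters via config instead
    else:
        prof, model = sim.desk_profile(), sim.desk_model()

    sets = sim.make_training_set(
        model, (40, 40), args.n_train, args.n_test, None, rng, prof, s=args.s
    )
    x_train, y_train, _ = instances_to_features(sets.train, prof.n_subwindows)
    x_test, y_test, _ = instances_to_features(sets.test, prof.n_subwindows)
    clf, report = train_classifier(
        (x_train, y_train), (x_test, y_test), rng=np.random.default_rng(args.seed + 1)
    )

    binary = float(
        np.mean((clf.predict(x_test) != 0) == (y_test != "neutral"))
    )
    outdir = pathlib.Path(args.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    clf.save(str(outdir / "classifier.npz"))
    payload = {
        "n_train_per_class": args.n_train,
        "n_test_per_class": args.n_test,
        "accuracy": report.accuracy,
        "balanced_accuracy": report.balanced_accuracy,
        "binary_neutral_vs_selected_accuracy": binary,
        "precision": report.precision,
        "recall": report.recall,
        "confusion": report.confusion.tolist(),
        "classes": list(report.classes),
    }
    (outdir / "classifier_report.json").write_text(json.dumps(payload, indent=2))
    print(
        f"3-class accuracy {report.accuracy:.3f} (balanced "
        f"{report.balanced_accuracy:.3f}); neutral-vs-selected {binary:.3f}"
    )
    print("confusion (rows = true neutral/shared/divergent):")
    print(report.confusion)


if __name__ == "__main__":
    main()
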