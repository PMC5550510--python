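#!/usr/bin/env python
"""Run the full pipeline on the synthetic bundle and check recovery.

Preprocessing -> per-contrast DE (|log2FC| > 1, expression floor 5) ->
direction-specific vote counting -> consensus at votes >= 4, then
compares the recovered up signature with the planted truth.
"""

import logging
from pathlib import Path

from votesig.pipeline import run_pipeline

BASE = Path(__file__).resolve().parent.parent / "results"


def read_truth_set(key: str) -> set[str]:
    for line in (BASE / "bundle" / "truth.txt").read_text().splitlines():
        if line.startswith(key + "\t"):
            payload = line.split("\t")[1]
            return {g for g in payload.split(",") if g}
    return set()


def main() -> None:
    logging.basicConfig(level=logging.INFO, format="%(levelname)s %(name)s: %(message)s")
    manifest = run_pipeline(BASE / "bundle" / "config.yaml", BASE / "run")
    sig = [
        line.split("\t")[0]
        for line in (BASE / "run" / "signature_up.tsv").read_text().splitlines()[1:]
    ]
    truth_up = read_truth_set("consensus_up")
    missed = truth_up - set(sig)
    extra = set(sig) - truth_up
    print(f"up signature: {len(sig)} genes; planted: {len(truth_up)}")
    print(f"missed: {sorted(missed) or 'none'}; spurious: {sorted(extra) or 'none'}")
    print("outputs:", ", ".join(manifest.outputs))


if __name__ == "__main__":
    main()
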