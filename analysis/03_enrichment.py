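#!/usr/bin/env python
"""Summarize term enrichment of the recovered up signature.

The pipeline run (02) already wrote enrichment.tsv (EASE statistic, BH
adjustment); this driver reports the top terms and whether the planted
term ranks first.
"""

from pathlib import Path

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    lines = (BASE / "run" / "enrichment.tsv").read_text().splitlines()
    planted = next(
        line.split("\t")[1]
        for line in (BASE / "bundle" / "truth.txt").read_text().splitlines()
        if line.startswith("enriched_term\t")
    )
    print(lines[0])
    for line in lines[1:6]:
        print(line)
    top = lines[1].split("\t")[0]
    print(f"planted term {planted} ranks {'first' if top == planted else 'NOT first'}")


if __name__ == "__main__":
    main()
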