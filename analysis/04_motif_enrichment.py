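#!/usr/bin/env python
"""Summarize promoter-proximal motif enrichment of the up signature.

The pipeline run (02) scanned signature vs background promoters with
the planted NFkB-like PWM and ten random decoys (ZOOPS hits at 80% of
the maximum log-odds, hypergeometric p, BH across motifs); this driver
reports the ranking.
"""

from pathlib import Path

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    lines = (BASE / "run" / "motif_enrichment.tsv").read_text().splitlines()
    print(lines[0])
    for line in lines[1:6]:
        print(line)
    top = lines[1].split("\t")[0]
    print(f"top-ranked motif: {top} ({'the planted motif' if top == 'SYN_NFKB_LIKE' else 'a decoy!'})")


if __name__ == "__main__":
    main()
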