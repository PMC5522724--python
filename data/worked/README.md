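# Worked-example matrices (not redistributed)

The acceptance checks compare this pipeline's output against worked
examples published in journal archives.  The matrices themselves are not
redistributed; to run those checks, place plain-text relaxed PHYLIP copies
here under the following names (taxon labels as printed in the sources;
the designated outgroup is set by `hennig.datasets.WORKED_EXAMPLES`):

| file | contents | outgroup |
| --- | --- | --- |
| `matrix17.phy` | Nelson & Platnick's matrix 17, character four removed (4 binary characters) | `O` |
| `kluge_table2.phy` | Kluge's table 2 (9 binary characters) | `X` |
| `kluge_table3.phy` | Kluge's table 3 (6 binary characters) | `X` |
| `harvey_fig5.phy` | Harvey's figure-5 matrix (23 binary characters) | `O` |
| `matrix_z.phy` | Farris's matrix Z (Kluge's table 3, every column doubled) | `O` |
| `hypothetical_dna.phy` | the hypothetical non-clock DNA matrix (MP length 33) | `O` |

Format example:

```
5 3
O  000
A  000
B  110
C  101
D  011
```

With the files in place, `pytest tests/test_acceptance.py` runs the
published-value checks and `scripts/acceptance.py` includes the
corresponding targets in its JSON report.
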