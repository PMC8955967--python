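# circsponge

Design and in-silico validation of **circular miRNA sponge constructs**.

A miRNA sponge is a transcript carrying multiple tandem miRNA binding
sites (MBS) that competitively sequester a target miRNA, de-repressing its
natural targets. Expressing the sponge as a circular RNA — by placing the
insert between inverted ALU elements so it is excised and covalently
closed during back-splicing — protects it from exonucleolytic decay, and a
central *bulge* of deliberate mismatches opposite the miRNA's mid-region
prevents AGO2-mediated slicing of the sponge itself. `circsponge`
automates this design for any target miRNA and checks the result before
synthesis. The worked example throughout is hsa-miR-21-5p, an oncomiR
upregulated in non-small cell lung cancer.

## The design model

For a target miRNA of length *L* (5'→3' positions 1..*L*, seed at 2–8),
each MBS is the reverse complement of the miRNA except over a bulge
window *B* (default miRNA positions 10–13): MBS position *q* faces miRNA
position *L*+1−*q*, and

- outside *B*, the MBS carries the Watson–Crick complement;
- inside *B*, it carries a base that neither WC- nor G:U-wobble-pairs the
  opposing miRNA base (default "identity" policy: the miRNA's own base,
  which is non-pairing for all four nucleotides and needs no RNG).

The insert is then

```
EcoRV · (MBS · spacer)×(n−1) · MBS · SacII      n = 7, |spacer| = 4
```

with spacers chosen by seeded search so that no new target seed match
(6mer or better) and no forbidden restriction recognition sequence
(EcoRV, SacII, plus HindIII/EcoRI, which frame the EGFP reporter on the
vector) is created in context. For the 22-nt miR-21 the default insert is
6 + 7·22 + 6·4 + 6 = **190 bp**. Back-splicing is modelled at sequence
level: the circle is exactly the insert's transcript joined end-to-start.

The site scanner classifies hits with the canonical seed taxonomy (6mer,
7mer-A1, 7mer-m8, 8mer — perfect WC over the defining window, wobble
counts as non-pairing) plus full-length classes (`full_perfect`,
`full_bulged`); the duplex reporter gives a positional pairing string
('|' WC, 'o' wobble, '.' mismatch) and the score n_wc + 0.5·n_wobble −
n_mismatch. Closed-form assay metrics (2^−ΔΔCt relative expression,
spheroid volume V = a·b²·π/6, relative volume and percent inhibition) are
included for companion analyses.

## Worked example

```
$ circsponge design --seq UAGCUUAUCAGACUGAUGUUGA --id hsa-miR-21-5p \
      --seed 1 --out-prefix demo/sponge
hsa-miR-21-5p	190	OK
```

This writes `demo/sponge.gb` (GenBank with the 15-feature table: 2 flanks
+ 7 MBS + 6 spacers), `demo/sponge.fasta`, and a validation report:

```
check	passed	detail
site_count	True	found 7 full sites, expected 7
mbs_duplexes	True	all MBS pair seed perfectly with bulge-only mismatches
forbidden_sites	True	no internal forbidden recognition sites
decoy_sites	True	20 decoys, none with >=7mer matches
feature_tiling	True	features tile the insert exactly
```

The duplex between miR-21 and one binding site shows perfect seed pairing
and the four-base central bulge (18 WC pairs, 4 mismatches, score 14):

```
miRNA 3'-AGUUGUAGUCAGACUAUUCGAU-5'
         |||||||||....|||||||||
site  5'-UCAACAUCACAGAGAUAAGCUA-3'
```

Back-splicing the construct and asking for the junction region returns
the 12-nt window `CCGCGGGAUAUC` — the SacII end joined to the EcoRV
start, the region a circle-specific (divergent) RT-PCR primer pair must
span:

```
$ circsponge circ demo/sponge.gb -w 6
...
# junction_window	CCGCGGGAUAUC
```

Other subcommands: `scan` (hit tables for sequence/miRNA panels, BED-like
TSV), `validate` (re-check a GenBank construct, nonzero exit on failure),
`metrics` (batch 2^−ΔΔCt or spheroid-volume tables). Everything is also
available as a library (`import circsponge`).

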