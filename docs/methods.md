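# Methods

## The construct model

`circsponge` models a circular miRNA sponge at pure sequence level. The
object of interest is a DNA insert destined for directional cloning
between two inverted ALU elements downstream of a CMV promoter; during
back-splicing the region between the ALU arms is excised and covalently
closed, so the mature product is a circular RNA consisting of the
insert's transcript. The package therefore works with three linked
representations: the DNA insert (sense strand = transcript with T for U),
its feature table, and the circular transcript.

The ALU arms, the promoter, and the EGFP reporter are *not* modelled as
sequence: the vector's ALU sequences are not public in any form we can
embed, and the reporter sits outside the ALU pair, so it is not part of
the circle. The circle is modelled as exactly the insert, with the
EcoRV/SacII flank bases retained (they lie inside the circularized
region); whether the synthesized circle retains them post-splicing is not
experimentally established, and retaining them is the conservative
sequence-level choice. The canonical rotation starts at the first base of
flank5 so circle coordinates coincide with insert coordinates, and the
back-splice junction is where the insert's 3' end meets its 5' start.

## Binding-site geometry

Pairing is strictly antiparallel and gap-free: MBS position *q* faces
miRNA position *L*+1−*q*. This is an idealization — a real bulged site
forms a loop with its own geometry — but the designed MBS has the same
length as the miRNA, so a positional model captures everything the design
controls. G:U wobble is classified as *non-pairing* throughout (site
classes and bulge construction alike); this is the conservative choice
for both on-target verification (a wobble in the seed would weaken
capture) and bulge design (a wobble-paired "bulge" base could restore
slicing-competent geometry).

The bulge window is expressed in **miRNA coordinates**. The construct
this package reproduces specifies the bulge at MBS positions 10–13; for a
22-nt miRNA these face miRNA positions 10–13, so the readings coincide
for miR-21. For other lengths we keep the miRNA-coordinate reading,
because the bulge's biological function is to mispair the miRNA's central
region (the AGO2 cleavage site, positions ~9–13) regardless of site
length. The window is a parameter (`bulge_window`), so users who prefer
the MBS-coordinate reading, or the 9–12 window quoted in parts of the
sponge literature, can set it; the validator refuses windows overlapping
the seed, since seed pairing is what captures the miRNA at all.

### Mismatch policy

The source construct does not state which bases were placed in the bulge.
The default `identity` policy puts the miRNA's own base opposite itself:
for every nucleotide X, the X:X opposition is neither Watson–Crick nor
wobble, so the non-pairing invariant holds by a four-case argument with
no randomness. `seeded_random` instead draws uniformly from the bases
that neither WC- nor wobble-pair the opposing base ({A,C,G} opposite A,
{A,C,U} opposite C, {A,G} opposite G, {C,U} opposite U), reproducible per
seed. Identity is the default because it makes designs byte-reproducible
with no RNG at all.

### Spacers

Only the spacer *length* (default 4 nt) is specified by the procedure the
package implements; composition is a free choice. The default is a seeded
rejection search: candidates are drawn uniformly over RNA 4-mers and
rejected if, in the window (left MBS + spacer + right MBS), any target
seed match of class 6mer or better, or any forbidden restriction
recognition sequence, overlaps the spacer positions. This is the minimal
safety constraint beyond length: a spacer must not create extra target
sites (they would be slicing-competent perfect sites) nor new cloning
sites. The search budget is 4096 attempts; exhaustion raises a design
error advising a different seed (for 4-mers the admissible set is large,
so this is only reachable with pathological custom enzyme sets). Policy
`fixed` (default) computes one admissible spacer from the seed and reuses
it between every MBS pair; `seeded_search` draws each gap independently
from the flowing RNG. Spacers sit only *between* MBS — n−1 of them —
never outside the outermost sites.

### Restriction enzymes

Recognition sequences come from Biopython's REBASE tables
(`Bio.Restriction`): EcoRV GATATC, SacII CCGCGG, HindIII AAGCTT, EcoRI
GAATTC. The four defaults are palindromic, so sense-strand scanning
covers both strands; non-palindromic user enzymes are additionally
scanned via the reverse complement of their recognition sequence.
HindIII/EcoRI are forbidden inside the insert because they frame the
EGFP reporter elsewhere on the vector and must remain unique.

## Scanning

Seed matches use the canonical taxonomy: a hit is anchored at a hexamer
pairing miRNA positions 2–7 and extended to 7mer-m8 (position 8 pairs)
and/or 7mer-A1 (an A faces position 1 — the site's adenine, regardless of
the miRNA's first base); 8mer is both. Each core is reported once with
its largest class. Full-length sites are miRNA-sized windows pairing WC
everywhere except (optionally) inside the declared bulge window,
classified `full_perfect` or `full_bulged`, with mismatch positions
reported in miRNA coordinates. Circular inputs use the doubled-sequence
technique — scan text+text, keep hits whose start lies in the first copy,
flag hits extending past the origin as junction-spanning. Overlapping
hits are all reported; deduplication is left to callers. No
thermodynamics: context scores, conservation, and 3'-supplementary
pairing are out of scope, since the designed sites are (near-)perfect and
the scanner's job is verification and off-target screening, not target
prediction.

## Validation checklist

`validate_construct` reports pass/fail (never raises) on: (a) exactly
n_mbs full target sites; (b) every MBS duplex pairs the seed perfectly
and mismatches exactly the bulge window; (c) no forbidden recognition
site inside the insert, the two terminal flanks exempted; (d) no decoy
miRNA has a 7mer-or-better seed match anywhere in the transcript —
6mers are tolerated because chance hexamer complements are ubiquitous in
any ~190-nt sequence and carry little repression on their own; (e) the
feature table tiles the insert exactly.

## Synthetic fixtures and what they do not show

`fixtures.random_mirna` draws uniform-random miRNA-like sequences of
length 20–24 with GC content in [0.2, 0.8] — length bounds matching
mature miRNAs, GC bounds excluding only degenerate extremes.
`generate_decoy_panel` rejection-samples decoys sharing no 6mer seed
complement with the target, the property the off-target check needs.
`random_design_target` additionally rejects targets whose own binding
site embeds a forbidden recognition sequence (for such a target the
design is infeasible as parameterized — a practitioner would switch
enzymes, and the validator reports the collision honestly if forced).
Random uniform sequences do not reproduce real miRNA base composition,
family structure, or 3'-isomiR variability, so passing the random-panel
suites shows the machinery is self-consistent, not that off-target rates
on real transcriptomes are negligible.

Test and demo problem sizes (20-decoy panels, 50-design validation
sweeps, rotation checks over a 190-nt circle) were chosen so the entire
suite completes in seconds while still exercising every code path at the
construct's true scale — the reference design itself is only 190 bp, so
nothing is scaled down from the real use case.

## Numerical and interface choices

Internal coordinates are 0-based half-open; all user-facing output
(duplex positions, bulge windows, GenBank locations) is 1-based
inclusive. Circular equality canonicalizes by lexicographically minimal
rotation (Booth's algorithm), making equality and hashing deterministic.
One global RNG seed flows from the CLI/config into every stochastic
choice (spacer search, decoy panels). The duplex score n_wc +
0.5·n_wobble − n_mismatch is an ordinal design aid with configurable
weights, not an energy. The 2^−ΔΔCt metric warns (does not fail) on Ct
values outside 0–45; percent inhibition takes its baseline as an explicit
argument because both untreated and reporter-only controls are defensible
baselines. GenBank output uses "DNA linear" for inserts and "RNA
circular" for transcripts, with design parameters round-tripped through
tagged COMMENT lines.

## Known limitations

Byte-identity with the originally synthesized wet-lab insert cannot be
verified: the published procedure does not disclose the exact bulge bases
or spacer sequences used. Splicing efficiency, ALU pairing, secondary
structure, and binding thermodynamics are not modelled; a design that
passes every check here can still circularize poorly or fold its MBS into
inaccessible structure. The assay metrics implement the standard
closed-form definitions only (no amplification-efficiency correction, no
growth-curve fitting).
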