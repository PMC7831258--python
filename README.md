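# resdist

Multi-task inter-residue distance prediction from multiple sequence
alignments. From one or two MSAs per target the pipeline computes
co-evolutionary feature tensors (covariance, precision/inverse-covariance,
and pseudolikelihood-maximization Potts couplings, plus scalar 2-D
statistics), feeds them through four residual convolutional branch networks
that simultaneously emit a real-value distance map and a 25-bin distogram,
ensembles the per-branch/per-MSA outputs, and converts them into contact
maps, evaluation metrics, and Cβ–Cβ distance restraints for
distance-geometry folding.

Because no GPU deep-learning framework is assumed, the networks run on a
small in-repo reverse-mode autograd engine (`resdist.nn.autograd`, pure
numpy with im2col convolutions) whose gradients are verified against finite
differences in the test suite. Default architectures match the published
geometry (483/482/484 input channels; Maxout reduction to a 64-channel
trunk; 16/20/16/22 residual blocks for the COV/PLM/PRE/OTHER branches; dual
ReLU-regression and 25-way softmax heads); desk-scale overrides
(`trunk_width`, `residual_blocks`, epochs) keep training runnable in
minutes on one CPU.

## Layout

| module | role |
|---|---|
| `resdist.msa` | FASTA/A3M/aln readers, identity-based sequence weights, Neff, weighted column/pair frequencies |
| `resdist.coevolution` | COV/PRE/PLM pair tensors, APC-corrected coupling contact score, MI / entropies / Pearson / contact-potential statistics |
| `resdist.features` | 1-D features (profile, SS/SA substitutes or external tables), pairwise expansion, branch input assembly with channel manifests |
| `resdist.nn` | autograd engine, RCIN / Maxout / SE blocks, the four branch networks, Adam/SGD, checkpoints |
| `resdist.training` | masked MSE + distogram cross-entropy, batch-of-1 Adam→SGD schedule, top-L/2 validation metric, multi-task vs regression-only comparison |
| `resdist.distmaps` | 25-bin scheme, distogram↔real-distance↔contact conversions, ensembling, RR/matrix I/O |
| `resdist.evaluation` | top-L/k long-range contact precision, 16 Å-filtered MSE, Pearson correlation |
| `resdist.restraints` | restraint generation (≤15 Å, sep ≥3, ±0.1 Å bounds), five nested cutoff subsets, CNS `.tbl` output, violation scoring against PDB coordinates |
| `resdist.synthetic` | seeded toy backbones, planted-coupling Potts MSA simulation, paired training fixtures |
| `resdist.cli` | `resdist` command-line pipeline |

## CLI

```bash
resdist synthesize --n-targets 3 --length 30 --seed 1 --out fixtures/
resdist features fixtures/t0.fasta --branches COV,OTHER --out feats/
resdist train --config train.yaml --out run/ --seed 1
resdist predict fixtures/t0.fasta fixtures/t1.fasta \
    --checkpoints run/COV.checkpoint,... --out pred/
resdist evaluate pred/target.realdist.txt fixtures/t0.pdb --out eval/
resdist restraints pred/target.realdist.txt --out restr/
```

Each command writes a resolved-config snapshot next to its outputs and is
deterministic given its seed. With two MSAs and four branch checkpoints,
`predict` averages 8 intermediate maps per output type (4 with one MSA).

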