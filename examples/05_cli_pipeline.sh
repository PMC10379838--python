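#!/bin/sh
# Full pipeline from the shell: synthesize a study fixture, call markers,
# analyze regional structure, and run a founder-size power grid.
# Outputs land under runs/demo/{simulate,calls,analysis,power}.
set -e

cat > /tmp/haplomig_demo.yaml <<'EOF'
seed: 7
simulate:
  source: {singleton_rate: 0.0}
  south: {n_destinations: 8, n_sampled: 30, source: {i65del_freq: 0.10}}
  north: {n_founders: 5, n_destinations: 8, n_sampled: 30,
          source: {i65del_freq: 0.32}}
power:
  founder_sizes: [5, 50, 500]
  replicates: 200
EOF

haplomig simulate -c /tmp/haplomig_demo.yaml -o runs/demo
haplomig call     -c /tmp/haplomig_demo.yaml -o runs/demo
haplomig analyze  -c /tmp/haplomig_demo.yaml -o runs/demo
haplomig power    -c /tmp/haplomig_demo.yaml -o runs/demo

echo "--- analysis report ---"
cat runs/demo/analysis/report.txt
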