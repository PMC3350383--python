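{
 "acceptor_sites.synthetic.txt": {
  "sha256": "15f93d00f740e2663fb4b5d842332799bd839578af2a5c2df74a93213494ff1f",
  "synthetic": true
 },
 "donor_sites.synthetic.txt": {
  "sha256": "db0337bbeb50544fa798870884a5dad723427352a06c3d54557f0e6f43fd4ab1",
  "synthetic": true
 },
 "duplex_params.json": {
  "sha256": "54237691ab3b580d7bb16da33037720fc366ac70ea2e05204497fec1bb89e502",
  "synthetic": false
 },
 "fas_ess_hex2.synthetic.txt": {
  "sha256": "51081a618e8db81e22eb9116816c8fe2bbe9ae6d992fd700345d02f745927760",
  "synthetic": true
 },
 "fas_ess_hex3.synthetic.txt": {
  "sha256": "835f37bdf7a6a9bc5eeb010192ee92b8c8cf2c65efb65b13d8abff163578d056",
  "synthetic": true
 },
 "group_signatures.tsv": {
  "sha256": "2ba4f2db13c4651c33bb8b116f352861e0b20f61a52926cc668c7a7b82ab9746",
  "synthetic": false
 },
 "maxent_lite_acceptor.synthetic.tsv": {
  "sha256": "2f90d3c4d90f9a6355c8f3d64b7e2a7c5bd485285dea908e32e82598436d1ddd",
  "synthetic": true
 },
 "maxent_lite_donor.synthetic.tsv": {
  "sha256": "74143b75d754bf94dcace3315b731dba1d72b7bf93619d67583c5379a30e632e",
  "synthetic": true
 },
 "pese_octamers.synthetic.txt": {
  "sha256": "29e96b0e069ed7671d72da29aeef7fd1ce93a62ba3a9cf8df6106d70c3f3e8c5",
  "synthetic": true
 },
 "pess_octamers.synthetic.txt": {
  "sha256": "8577c18c64ccffb1642d60ba8827907947267112b4902d691b6287c92c22acc3",
  "synthetic": true
 },
 "reference_tree.json": {
  "sha256": "e9aba355fbc931ace7d0b7d037ec8769bee1fb0e0746111d19e2ba45b104b93d",
  "synthetic": false
 },
 "rescue_ese_hexamers.synthetic.txt": {
  "sha256": "dee9314c2eb50169ad8eee0fca9e8b745478ae85d805326bc46cbc943d1e68e8",
  "synthetic": true
 },
 "sc35.synthetic.tsv": {
  "sha256": "51646de4517b19504e8840964598ca6c1dcd2bc2f001ed4f33f5bcecb847dde0",
  "synthetic": true
 },
 "sf2_asf.synthetic.tsv": {
  "sha256": "8ccf111595a1f3ec0e9b5a432b945cd3d5c59cc0e85f6c05e72f4d3ca52eb538",
  "synthetic": true
 },
 "sf2_asf_igm_brca1.synthetic.tsv": {
  "sha256": "7e24f0d259e7411ba2cdc39f169eb1b3c08a785491db54603ff96984ce9c0b60",
  "synthetic": true
 },
 "shapiro_acceptor.synthetic.tsv": {
  "sha256": "0c1a70ae2e5419185037e1b172209febdd6af53572760954a7d4f8e9dc6dd06b",
  "synthetic": true
 },
 "shapiro_donor.synthetic.tsv": {
  "sha256": "13107d068ad91e5f669d623e09c19d96edb0fb0db20b255a92f0613b5663024b",
  "synthetic": true
 },
 "srp40.synthetic.tsv": {
  "sha256": "dc152c683b9b49d9f1e91a16690c8f912e8c3adcb76beb4d6ea7e5b3bcff5009",
  "synthetic": true
 },
 "srp55.synthetic.tsv": {
  "sha256": "79d10ea717bf69eeef25a0291300d446da16602116acba1114f15aea50580514",
  "synthetic": true
 }
}
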