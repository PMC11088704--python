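file	sha256
config.txt	4ef9feffb67189a1c51d959a22d5a8ad363352875adf351539aadbde8d62005b
peptide_free.pdb	52adabf0b3542f5e59babbc985cd1ae39d07dd8e08258c7a5f6a9e79a2dc6a81
pre_A360.tsv	2f9fa2865319d35344d9224c20c375bc95a4890dfa7ddc170f77e225ee9d951b
pre_A377.tsv	96a9d6ec308b1c2e87b463a75cc988784183453efd45340744ae5564309766e9
pre_A390.tsv	026ecd89d2fbd6a4b5e326640f1844cf68852ebcb68510eb2b22908cec423f8c
receptor.pdb	57a0cf5da80b98b7d825888ce07013db33f9a2c5c404b37cf4ea1b7c2ac2b38f
restraints_mutagenesis.tsv	cd19f44e5f619bad1d966cf9b7ff2c05199b589cdab7280fcbb4f0db9801e2f0
shifts_bound.tsv	b0c31061fd2beea3e9afbdd79f941709808a6055d20d9084429967db8c4b7a74
shifts_free.tsv	ea9f52b4fbd55cee00b535bd2eac58be25edb6fdcba7c8a0099cb068a7d81dd4
truth_complex.pdb	b23030f6dcea5ba9e5a547046ec72a168ed208c72d82dced89649b3ad26cb27d
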