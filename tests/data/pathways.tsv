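# version: toy-path-seed2024
pathway_id	pathway_name	members
PW0001	pathway ragura	HMDB9000013|HMDB9000016|HMDB9000017|HMDB9000023
PW0002	pathway tobufe	HMDB9000009|HMDB9000016|HMDB9000020|HMDB9000021
PW0003	pathway tafibo	HMDB9000001|HMDB9000003|HMDB9000012|HMDB9000014
PW0004	pathway nitemi	HMDB9000007|HMDB9000016|HMDB9000018|HMDB9000022
PW0005	pathway podepi	HMDB9000005|HMDB9000007|HMDB9000008|HMDB9000010
PW0006	pathway damobo	HMDB9000001|HMDB9000010|HMDB9000018|HMDB9000019
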