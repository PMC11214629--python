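# KEGG Orthology identifiers of bacterial ribosomal proteins, used to exclude
# ribosomal functions from the top-KO correlation selection.
K02863	large subunit ribosomal protein L1
K02886	large subunit ribosomal protein L2
K02906	large subunit ribosomal protein L3
K02926	large subunit ribosomal protein L4
K02931	large subunit ribosomal protein L5
K02933	large subunit ribosomal protein L6
K02935	large subunit ribosomal protein L7/L12
K02939	large subunit ribosomal protein L9
K02864	large subunit ribosomal protein L10
K02867	large subunit ribosomal protein L11
K02871	large subunit ribosomal protein L13
K02874	large subunit ribosomal protein L14
K02876	large subunit ribosomal protein L15
K02878	large subunit ribosomal protein L16
K02879	large subunit ribosomal protein L17
K02881	large subunit ribosomal protein L18
K02884	large subunit ribosomal protein L19
K02887	large subunit ribosomal protein L20
K02888	large subunit ribosomal protein L21
K02890	large subunit ribosomal protein L22
K02892	large subunit ribosomal protein L23
K02895	large subunit ribosomal protein L24
K02897	large subunit ribosomal protein L25
K02899	large subunit ribosomal protein L27
K02902	large subunit ribosomal protein L28
K02904	large subunit ribosomal protein L29
K02907	large subunit ribosomal protein L30
K02909	large subunit ribosomal protein L31
K02911	large subunit ribosomal protein L32
K02913	large subunit ribosomal protein L33
K02914	large subunit ribosomal protein L34
K02916	large subunit ribosomal protein L35
K02919	large subunit ribosomal protein L36
K02945	small subunit ribosomal protein S1
K02967	small subunit ribosomal protein S2
K02982	small subunit ribosomal protein S3
K02986	small subunit ribosomal protein S4
K02988	small subunit ribosomal protein S5
K02990	small subunit ribosomal protein S6
K02992	small subunit ribosomal protein S7
K02994	small subunit ribosomal protein S8
K02996	small subunit ribosomal protein S9
K02946	small subunit ribosomal protein S10
K02948	small subunit ribosomal protein S11
K02950	small subunit ribosomal protein S12
K02952	small subunit ribosomal protein S13
K02954	small subunit ribosomal protein S14
K02956	small subunit ribosomal protein S15
K02959	small subunit ribosomal protein S16
K02961	small subunit ribosomal protein S17
K02963	small subunit ribosomal protein S18
K02965	small subunit ribosomal protein S19
K02968	small subunit ribosomal protein S20
K02970	small subunit ribosomal protein S21
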