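osa00940	Anchor pathway for met_0001	gene_0000	gene_0002	gene_0006	gene_0009	gene_0011	gene_0013	gene_0017	gene_0018	gene_0019	met_0001
osa00941	Anchor pathway for met_0000	gene_0000	gene_0004	gene_0005	gene_0006	gene_0008	gene_0010	gene_0011	gene_0014	gene_0018	met_0000
ko00196	Photosynthesis - antenna proteins	gene_0000	gene_0001	gene_0002	gene_0003	gene_0004	gene_0005	gene_0006	gene_0007	gene_0008	gene_0009	gene_0010	gene_0011	gene_0012	gene_0013	gene_0014	gene_0015	gene_0016	gene_0017	gene_0018	gene_0019
ko00710	Carbon fixation in photosynthetic organisms	gene_0000	gene_0001	gene_0002	gene_0003	gene_0004	gene_0005	gene_0006	gene_0007	gene_0008	gene_0009	gene_0010	gene_0011	gene_0012	gene_0013	gene_0014	gene_0015	gene_0016	gene_0017	gene_0018	gene_0019
ko00720	Carbon fixation pathways in prokaryotes	gene_0000	gene_0001	gene_0002	gene_0003	gene_0004	gene_0005	gene_0006	gene_0007	gene_0008	gene_0009	gene_0010	gene_0011	gene_0012	gene_0013	gene_0014	gene_0015	gene_0016	gene_0017	gene_0018	gene_0019
ko00195	Photosynthesis	gene_0000	gene_0001	gene_0002	gene_0003	gene_0004	gene_0005	gene_0006	gene_0007	gene_0008	gene_0009	gene_0010	gene_0011	gene_0012	gene_0013	gene_0014	gene_0015	gene_0016	gene_0017	gene_0018	gene_0019
ko00190	Oxidative phosphorylation	gene_0000	gene_0001	gene_0002	gene_0003	gene_0004	gene_0005	gene_0006	gene_0007	gene_0008	gene_0009	gene_0010	gene_0011	gene_0012	gene_0013	gene_0014	gene_0015	gene_0016	gene_0017	gene_0018	gene_0019
GO:0006970	synthetic GO term 0	gene_0000	gene_0001	gene_0002	gene_0003	gene_0004	gene_0005	gene_0006	gene_0007	gene_0008	gene_0009	gene_0010	gene_0011	gene_0012	gene_0013	gene_0014	gene_0015	gene_0016	gene_0017	gene_0018	gene_0019
GO:0006971	synthetic GO term 1	gene_0000	gene_0001	gene_0002	gene_0003	gene_0004	gene_0005	gene_0006	gene_0007	gene_0008	gene_0009	gene_0010	gene_0011	gene_0012	gene_0013	gene_0014	gene_0015	gene_0016	gene_0017	gene_0018	gene_0019
GO:0006972	synthetic GO term 2	gene_0000	gene_0001	gene_0002	gene_0003	gene_0004	gene_0005	gene_0006	gene_0007	gene_0008	gene_0009	gene_0010	gene_0011	gene_0012	gene_0013	gene_0014	gene_0015	gene_0016	gene_0017	gene_0018	gene_0019
GO:0006973	synthetic GO term 3	gene_0000	gene_0001	gene_0002	gene_0003	gene_0004	gene_0005	gene_0006	gene_0007	gene_0008	gene_0009	gene_0010	gene_0011	gene_0012	gene_0013	gene_0014	gene_0015	gene_0016	gene_0017	gene_0018	gene_0019
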