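code,name,role_flags
1,Broadleaf Evergreen Forest,
2,Broadleaf Deciduous Forest,
3,Needleleaf Evergreen Forest,
4,Needleleaf Deciduous Forest,
5,Mixed Forest,
6,Tree Open,
7,Shrub,
8,Herbaceous,
9,Herbaceous with Sparse Tree/Shrub,
10,Sparse vegetation,
11,Cropland,agricultural_strict;agricultural_selection
12,Paddy field,agricultural_strict;agricultural_selection
13,Cropland/Other Vegetation Mosaic,agricultural_selection
14,Mangrove,
15,Wetland,
16,"Bare Area, Consolidated (Gravel, Rock)",
17,"Bare Area, Unconsolidated (Sand)",
18,Urban,urban
19,Snow/Ice,
20,Water Bodies,
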