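pdb,category,aspdock_hits,srm_hits
1ahw,antibody,0,8
1bgx,antibody,0,0
1bj1,antibody,0,0
1bvk,antibody,3,60
1dqj,antibody,0,3
1e6j,antibody,0,24
1fsk,antibody,0,57
1i9r,antibody,0,6
1iqd,antibody,3,65
1jps,antibody,7,37
1k4c,antibody,0,0
1mlc,antibody,0,52
1nby,antibody,0,1
1nca,antibody,0,28
1nsn,antibody,2,59
1vfb,antibody,0,63
1wej,antibody,0,2
2fd6,antibody,0,10
2hmi,antibody,0,0
2jel,antibody,3,64
2vis,antibody,0,0
1a2y,dockground,3,2
1cgj,dockground,84,64
1cse,dockground,6,6
1f7z,dockground,7,5
1ppf,dockground,39,30
1shw,dockground,25,19
1tx4,dockground,25,21
1uex,dockground,5,4
2jb0,dockground,11,10
2kai,dockground,20,13
2pav,dockground,25,22
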